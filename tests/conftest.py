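import pytest

import ginirisk as gr

# Published per-site summary table (Nordic twin registry estimates):
# site -> (h2 %, env2 %, lifetime risk %, lambda_M, GC_h2, GC_beta,
#          RR_20:20, RR_interv) with the derived columns as printed.
PUBLISHED_TABLE = {
    "Overall cancer": (33.0, 0.0, 32.4, 1.4, 0.37, 0.37, 9, 0.64),
    "Head and neck": (9.0, 26.0, 0.8, 7.5, 0.45, 0.84, 12, 0.55),
    "Stomach": (22.0, 6.0, 1.1, 6.2, 0.64, 0.81, 66, 0.34),
    "Colon": (15.0, 16.0, 2.9, 3.8, 0.48, 0.71, 16, 0.51),
    "Rectum and anus": (14.0, 10.0, 1.9, 3.5, 0.49, 0.68, 17, 0.50),
    "Lung": (18.0, 24.0, 3.2, 5.5, 0.52, 0.80, 22, 0.48),
    "Melanoma": (58.0, 0.0, 1.2, 16.3, 0.90, 0.93, 69946, 0.05),
    "Non-Melanoma": (43.0, 0.0, 1.9, 7.6, 0.79, 0.85, 997, 0.17),
    "Breast": (31.0, 16.0, 9.4, 3.0, 0.55, 0.66, 36, 0.45),
    "Corpus uteri": (27.0, 0.0, 2.0, 3.5, 0.66, 0.69, 87, 0.33),
    "Ovary": (39.0, 0.0, 1.6, 5.4, 0.78, 0.79, 610, 0.19),
    "Prostate": (57.0, 0.0, 10.5, 3.6, 0.71, 0.73, 689, 0.26),
    "Testis": (37.0, 24.0, 0.5, 27.6, 0.83, 0.96, 1339, 0.13),
    "Kidney": (38.0, 0.0, 0.8, 8.4, 0.81, 0.85, 1049, 0.15),
    "Bladder, other urinary organs": (30.0, 0.0, 2.2, 4.5, 0.68, 0.75, 120, 0.30),
    "Leukemia, other": (57.0, 0.0, 0.6, 25.3, 0.92, 0.95, 181350, 0.03),
}


@pytest.fixture(scope="session")
def prostate():
    """Probit risk distribution for prostate cancer (h2 = 0.57, risk = 10.5%)."""
    return gr.probit_risk_distribution(0.57, 0.105)


@pytest.fixture(scope="session")
def overall_cancer():
    """Probit risk distribution for any-cancer risk (h2 = 0.33, risk = 32.4%)."""
    return gr.probit_risk_distribution(0.33, 0.324)


@pytest.fixture(scope="session")
def uniform_risk():
    """Beta(1, 1): uniformly distributed risk, with known closed forms."""
    return gr.BetaRiskDistribution(1.0, 1.0)


@pytest.fixture(scope="session")
def packaged_records():
    return gr.load_table()
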