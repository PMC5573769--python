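"""Published GBD 2015 summary estimates for COPD and asthma.

Point estimates from the published 2015 global summary tables (counts in
thousands; attribution shares in percent of DALYs), used as reference
inputs for the accounting identities the pipeline's draw machinery must
reproduce — e.g. DALY = YLL + YLD row sums and the behavioural /
environmental attribution decomposition by SDI quintile.
"""

from __future__ import annotations

import importlib.resources

import pandas as pd

__all__ = ["load_summary", "load_attribution", "data_path"]


def data_path(name: str):
    return importlib.resources.files("respburden.data") / name


def load_summary() -> pd.DataFrame:
    """YLL/YLD/DALY/death/prevalence point estimates by cause and SDI stratum."""
    return pd.read_csv(data_path("gbd2015_summary.csv"))


def load_attribution() -> pd.DataFrame:
    """COPD DALY attribution shares (%) by SDI quintile: environmental-only,
    joint, behavioural-only, unattributed."""
    return pd.read_csv(data_path("gbd2015_attribution.csv"))
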