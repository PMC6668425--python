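"""Packaged observation fixture."""

from __future__ import annotations

from importlib import resources

import pandas as pd


def load_diet_ch4_observations() -> pd.DataFrame:
    """The packaged 43-record diet/enteric-methane signature table.

    A synthetic stand-in for the literature compilation of paired
    delta13C_diet / delta13C_CH4 observations from six source documents:
    constructed to carry the same sample size, diet-signature span,
    provenance split (27 directly reported diets, 16 composition-derived)
    and the same fitted-line statistics as the published compilation, with
    per-point uncertainty columns (``diet_sd``, ``ch4_sd``) reflecting the
    observed scatter.  Columns: species, delta13c_diet, diet_sd,
    delta13c_ch4, ch4_sd, year, provenance, source_id.
    """
    ref = resources.files("rumisotope.data").joinpath(
        "diet_ch4_observations_synthetic.csv"
    )
    with ref.open("r") as fh:
        return pd.read_csv(fh)
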