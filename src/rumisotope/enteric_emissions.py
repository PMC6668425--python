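"""IPCC Tier-2 enteric methane emissions.

Gross energy intake is feed dry matter times the mean gross-energy density
(18.45 MJ per kg DM); a methane conversion factor Y_m (6.5 %, the
wide-spread-diet default for cattle and mature sheep) converts gross energy
to methane via the energy content of CH4 (55.65 MJ per kg).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ruminant_energy import BASKET_POOLS, E_GE_FEED


@dataclass(frozen=True)
class EmissionParams:
    """Tier-2 parameters: Y_m = 6.5 % (95 % CI +/- 1.0 %), E_CH4 = 55.65 MJ/kg."""

    y_m: float = 0.065
    e_ch4: float = 55.65
    e_ge: float = E_GE_FEED

    def __post_init__(self):
        if not 0.0 <= self.y_m < 0.15:
            raise ValueError(f"Y_m = {self.y_m} outside [0, 0.15)")
        if self.e_ch4 <= 0 or self.e_ge <= 0:
            raise ValueError("energy constants must be positive")


def gross_energy(basket, e_ge: float = E_GE_FEED):
    """Gross energy intake (MJ): total dry matter of the basket times E_GE.

    ``basket`` is either a DataFrame with the six diet pools or an
    array/scalar of total dry matter (kg DM).
    """
    if isinstance(basket, pd.DataFrame):
        total = basket[list(BASKET_POOLS)].sum(axis=1).to_numpy(dtype=float)
    else:
        total = np.asarray(basket, dtype=float)
    if (total < 0).any():
        raise ValueError("dry matter must be non-negative")
    out = total * e_ge
    return float(out) if out.ndim == 0 else out


def enteric_ch4(ge, params: EmissionParams | None = None):
    """Enteric methane emission (Tg CH4) from gross energy intake (MJ).

    F = GE * Y_m / (E_CH4 * 1e9); linear in both GE and Y_m.
    """
    params = EmissionParams() if params is None else params
    ge = np.asarray(ge, dtype=float)
    if (ge < 0).any():
        raise ValueError("gross energy must be non-negative")
    out = ge * params.y_m / (params.e_ch4 * 1e9)
    return float(out) if out.ndim == 0 else out
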