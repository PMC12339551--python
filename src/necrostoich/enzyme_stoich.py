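"""Ecoenzymatic acquisition-ratio diagnostics.

The C:N:P acquisition ratios use the standard ecoenzymatic grouping:
C = BG + CBH (β-glucosidase + cellobiohydrolase), N = NAG + LAP
(N-acetyl-β-glucosaminidase + leucine aminopeptidase), P = AP (acid
phosphatase). Activities are in nmol g⁻¹ h⁻¹; ratios are dimensionless and
invariant to rescaling the panel. A natural-log variant (ratios of
ln-transformed activities, the form common in ecoenzymatic-stoichiometry
vector analyses) is available via ``log_transform=True``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


class EnzymeStoichError(ValueError):
    pass


@dataclass(frozen=True)
class EnzymePanel:
    """One sample's hydrolase activities, nmol g⁻¹ h⁻¹."""

    bg: float
    cbh: float
    nag: float
    lap: float
    ap: float

    def __post_init__(self):
        for name in ("bg", "cbh", "nag", "lap", "ap"):
            if getattr(self, name) < 0:
                raise EnzymeStoichError(f"{name} must be >= 0")


def acquisition_ratios(
    panel: EnzymePanel, *, log_transform: bool = False
) -> tuple[float, float, float]:
    """(C:N, C:P, N:P) acquisition-enzyme ratios.

    With ``log_transform`` each pooled activity is ln(1 + activity)-transformed
    before the ratios are taken.
    """
    c = panel.bg + panel.cbh
    n = panel.nag + panel.lap
    p = panel.ap
    if log_transform:
        c, n, p = np.log1p(c), np.log1p(n), np.log1p(p)
    if n == 0 or p == 0:
        raise EnzymeStoichError(
            "acquisition ratios undefined: zero N- or P-enzyme activity"
        )
    return c / n, c / p, n / p


def add_ratios(df, *, log_transform: bool = False):
    """Append enzyme C:N / C:P / N:P ratio columns to a covariate table."""
    needed = ("bg", "cbh", "nag", "lap", "ap")
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise EnzymeStoichError(f"covariate table missing enzyme columns: {missing}")
    out = df.copy()
    c = out["bg"].to_numpy(float) + out["cbh"].to_numpy(float)
    n = out["nag"].to_numpy(float) + out["lap"].to_numpy(float)
    p = out["ap"].to_numpy(float)
    if log_transform:
        c, n, p = np.log1p(c), np.log1p(n), np.log1p(p)
    if np.any(n == 0) or np.any(p == 0):
        raise EnzymeStoichError(
            "acquisition ratios undefined: zero N- or P-enzyme activity"
        )
    out["enzyme_cn"] = c / n
    out["enzyme_cp"] = c / p
    out["enzyme_np"] = n / p
    return out
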