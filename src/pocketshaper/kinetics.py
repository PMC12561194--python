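"""Michaelis–Menten fitting, efficiency/fold-change/TTN reporting, and
saturation-mutagenesis library arithmetic.

Initial-rate data ``(S, v)`` are fit to ``v = Vmax·S/(Km+S)`` by nonlinear
least squares initialised from the Hanes–Woolf linearisation;
``kcat = Vmax/[E]`` and the catalytic efficiency ``kcat/Km`` follow.
Published efficiency tables are conventionally printed at 2 decimals and
fold-changes at 1, with half-up rounding; both raw and rounded values are
always reported because fold-changes recomputed from rounded table entries
can differ from unrounded ratios.

Library design covers NNK single-site saturation mutagenesis: the NNK
degenerate codon (N = A/C/G/T, K = G/T) spans 32 equiprobable codons
encoding all 20 amino acids with multiplicities 3 (Leu/Arg/Ser),
2 (Ala/Gly/Pro/Thr/Val), 1 (the remaining twelve) plus one stop codon.
The number of clones needed for a target coverage confidence is the
smallest n with P(all 20 amino acids observed in n draws) ≥ confidence,
computed exactly by inclusion–exclusion grouped by multiplicity class.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from math import comb
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "KineticsFit",
    "ReportedEfficiency",
    "LibraryDesign",
    "TTNRecord",
    "NNK_MULTIPLICITIES",
    "fit_michaelis_menten",
    "catalytic_efficiency",
    "fold_change",
    "total_turnover",
    "library_total",
    "nnk_coverage_probability",
    "nnk_coverage_clones",
    "equiprobable_coverage_probability",
]

# amino-acid codon multiplicities under NNK: 3×3 + 5×2 + 12×1 (+1 stop) = 32
NNK_MULTIPLICITIES = {3: 3, 2: 5, 1: 12}
NNK_CODONS = 32


def round_half_up(value: float, decimals: int) -> float:
    """Decimal half-up rounding (0.005 → 0.01), as printed tables use."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class KineticsFit:
    km_mM: float
    vmax: float
    kcat_per_s: float
    efficiency: float  # kcat/Km, unrounded
    km_stderr: float
    vmax_stderr: float
    kcat_stderr: float
    n_points: int
    vmax_poorly_constrained: bool = False  # S_max < 2·Km


@dataclass(frozen=True)
class ReportedEfficiency:
    raw: float
    rounded_2dp: float

    def __post_init__(self):
        if abs(self.rounded_2dp - round_half_up(self.raw, 2)) > 1e-12:
            raise ValueError("rounded_2dp must be the half-up 2-decimal rounding")


@dataclass(frozen=True)
class LibraryDesign:
    n_sites: int
    clones_per_site: int
    total_clones: int
    coverage_target: float | None = None
    codon_scheme: str = "NNK"

    def __post_init__(self):
        if self.total_clones != self.n_sites * self.clones_per_site:
            raise ValueError("total_clones must equal n_sites × clones_per_site")


@dataclass(frozen=True)
class TTNRecord:
    product_formed: float
    enzyme: float
    ttn: float
    unit: str = ""


def _hanes_woolf_start(s: np.ndarray, v: np.ndarray) -> tuple[float, float]:
    """Direct linear estimate of (Km, Vmax) from S/v = S/Vmax + Km/Vmax."""
    pos = (s > 0) & (v > 0)
    if pos.sum() < 2:
        return float(np.median(s[s > 0]) if (s > 0).any() else 1.0), float(
            v.max() if v.size else 1.0
        )
    slope, intercept = np.polyfit(s[pos], s[pos] / v[pos], 1)
    vmax = 1.0 / slope if slope > 0 else float(v.max())
    km = intercept * vmax if intercept > 0 else float(np.median(s[pos]))
    return max(km, 1e-9), max(vmax, 1e-9)


def fit_michaelis_menten(
    data: pd.DataFrame,
    enzyme_conc: float,
    substrate_col: str = "substrate_mM",
    rate_col: str = "rate",
) -> KineticsFit:
    """Nonlinear least-squares Michaelis–Menten fit.

    Requires ≥ 4 distinct substrate levels and non-negative rates.
    Standard errors come from the local curvature (covariance of the
    least-squares solution).  A warning flag is set when S_max < 2·Km,
    where Vmax is poorly constrained by the grid.
    """
    s = np.asarray(data[substrate_col], dtype=float)
    v = np.asarray(data[rate_col], dtype=float)
    if enzyme_conc <= 0:
        raise ValueError("enzyme_conc must be > 0")
    if np.unique(s).size < 4:
        raise ValueError("need ≥ 4 distinct substrate levels")
    if np.any(v < 0):
        raise ValueError("rates must be non-negative")

    km0, vmax0 = _hanes_woolf_start(s, v)

    def mm(S, vmax, km):
        return vmax * S / (km + S)

    try:
        popt, pcov = curve_fit(
            mm,
            s,
            v,
            p0=(vmax0, km0),
            bounds=((0.0, 0.0), (np.inf, np.inf)),
            xtol=1e-12,
            ftol=1e-12,
            gtol=1e-12,
            maxfev=20000,
        )
    except RuntimeError as exc:
        raise RuntimeError(
            f"Michaelis–Menten fit did not converge (start Vmax={vmax0:.4g}, "
            f"Km={km0:.4g}): {exc}"
        ) from exc
    vmax, km = (float(p) for p in popt)
    perr = np.sqrt(np.clip(np.diag(pcov), 0.0, None))
    kcat = vmax / enzyme_conc
    return KineticsFit(
        km_mM=km,
        vmax=vmax,
        kcat_per_s=kcat,
        efficiency=kcat / km,
        km_stderr=float(perr[1]),
        vmax_stderr=float(perr[0]),
        kcat_stderr=float(perr[0] / enzyme_conc),
        n_points=int(s.size),
        vmax_poorly_constrained=bool(s.max() < 2.0 * km),
    )


def catalytic_efficiency(kcat: float, km: float) -> ReportedEfficiency:
    """kcat/Km with the 2-decimal half-up rounding used in printed tables."""
    if km <= 0:
        raise ValueError("Km must be > 0")
    raw = kcat / km
    return ReportedEfficiency(raw=raw, rounded_2dp=round_half_up(raw, 2))


def fold_change(numerator: float, denominator: float, decimals: int = 1) -> float:
    """Ratio rounded half-up to ``decimals`` (printed-table convention)."""
    if denominator <= 0:
        raise ValueError("denominator must be > 0")
    return round_half_up(numerator / denominator, decimals)


def total_turnover(product: float, enzyme: float, unit: str = "") -> TTNRecord:
    """Total turnover number: product formed per enzyme, same molar unit.

    ``unit`` tags both quantities; passing two different tags (separated
    by "/") is a contract violation.
    """
    if enzyme <= 0:
        raise ValueError("enzyme concentration must be > 0")
    if "/" in unit:
        raise ValueError(
            f"mismatched unit tags {unit!r}: product and enzyme must share "
            "one molar unit"
        )
    return TTNRecord(product_formed=product, enzyme=enzyme, ttn=product / enzyme, unit=unit)


def library_total(
    n_sites: int, clones_per_site: int, coverage_target: float | None = None
) -> LibraryDesign:
    """Screening total for single-site saturation over ``n_sites`` sites."""
    if n_sites < 1 or clones_per_site < 1:
        raise ValueError("n_sites and clones_per_site must be ≥ 1")
    return LibraryDesign(
        n_sites=n_sites,
        clones_per_site=clones_per_site,
        total_clones=n_sites * clones_per_site,
        coverage_target=coverage_target,
    )


def nnk_coverage_probability(n: int) -> float:
    """P(all 20 amino acids observed in n NNK draws), by inclusion–exclusion
    over missing-amino-acid subsets grouped by codon-multiplicity class."""
    if n < 20:
        return 0.0
    total = 0.0
    for a in range(NNK_MULTIPLICITIES[3] + 1):
        for b in range(NNK_MULTIPLICITIES[2] + 1):
            for c in range(NNK_MULTIPLICITIES[1] + 1):
                missing_codons = 3 * a + 2 * b + c
                ways = (
                    comb(NNK_MULTIPLICITIES[3], a)
                    * comb(NNK_MULTIPLICITIES[2], b)
                    * comb(NNK_MULTIPLICITIES[1], c)
                )
                sign = -1 if (a + b + c) % 2 else 1
                total += sign * ways * ((NNK_CODONS - missing_codons) / NNK_CODONS) ** n
    return float(min(max(total, 0.0), 1.0))


def equiprobable_coverage_probability(n: int, k: int = 20) -> float:
    """Idealised coupon-collector coverage: k equiprobable outcomes."""
    if n < k:
        return 0.0
    return float(
        sum((-1) ** j * comb(k, j) * (1 - j / k) ** n for j in range(k + 1))
    )


def nnk_coverage_clones(confidence: float) -> int:
    """Smallest clone count n with NNK coverage probability ≥ confidence."""
    if not 0.0 < confidence < 1.0:
        raise ValueError("confidence must be in (0, 1)")
    n = 20
    while nnk_coverage_probability(n) < confidence:
        n += 1
        if n > 100000:  # pragma: no cover - unreachable for sane confidence
            raise RuntimeError("coverage search did not terminate")
    return n
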