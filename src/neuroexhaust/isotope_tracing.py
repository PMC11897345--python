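"""Isotopologue analysis for [U-13C]glutamine tracing and metabolite panels.

Uniformly labelled glutamine enters the TCA cycle through glutamate and
2-oxoglutarate (all M+5). Oxidative flux (2-oxoglutarate -> succinate ->
... -> citrate) produces citrate M+4 and malate/aspartate M+4; reductive
carboxylation of 2-oxoglutarate to citrate produces citrate M+5 and, after
cleavage, malate/aspartate M+3. The ratio of the reductive to the
oxidative isotopologue (citrate M+5/M+4; malate or aspartate M+3/M+4)
therefore reads out flux direction: 1 means equal contribution from the
two routes, and under the single-turn model f_red = r / (1 + r).

Also here: total-peak-area normalisation of metabolite panels, optional
13C natural-abundance correction (non-negative least squares against the
binomial convolution matrix), fractional contribution
FC = sum(i * M_i) / (n * sum(M_i)), and group statistics with a
Shapiro-Wilk normality gate (parametric when every group passes, else
rank-based; the Kruskal-Wallis panel family is reported without post hoc
correction).
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import nnls

__all__ = [
    "FluxRatioResult",
    "RATIO_KINDS",
    "normalize_total_area",
    "compute_mid",
    "na_correct",
    "na_correct_table",
    "fractional_contribution",
    "flux_direction_ratio",
    "flux_ratio_table",
    "estimate_reductive_fraction",
    "compare_panels",
]

#: flux-direction ratio definitions: metabolite -> (numerator, denominator)
RATIO_KINDS: dict[str, tuple[int, int]] = {
    "citrate": (5, 4),     # reductive M+5 over oxidative M+4
    "malate": (3, 4),      # reductive M+3 over oxidative M+4
    "aspartate": (3, 4),
}

_ZERO_DENOM = 1e-6


def normalize_total_area(panel: pd.DataFrame,
                         sample_col: str = "sample",
                         area_col: str = "area") -> pd.DataFrame:
    """Total-peak-area normalisation: each peak area divided by the summed
    area of all peaks in the same sample, giving unitless relative
    abundances (column ``relative_abundance``; per-sample sum = 1)."""
    if (panel[area_col] < 0).any():
        raise ValueError("peak areas must be non-negative")
    totals = panel.groupby(sample_col)[area_col].transform("sum")
    if (totals == 0).any():
        bad = panel.loc[totals == 0, sample_col].unique()
        raise ValueError(f"sample(s) with all-zero areas: {list(bad)}")
    out = panel.copy()
    out["relative_abundance"] = panel[area_col] / totals
    return out


def compute_mid(intensities: Sequence[float]) -> np.ndarray:
    """Mass-isotopologue distribution from per-isotopologue intensities
    (M0..Mn for an n-carbon metabolite); fractions sum to 1."""
    x = np.asarray(intensities, dtype=float)
    if (x < 0).any():
        raise ValueError("intensities must be non-negative")
    total = x.sum()
    if total == 0:
        raise ValueError("all-zero intensity vector")
    return x / total


def _na_matrix(n: int, p13c: float) -> np.ndarray:
    """A[i, j] = P(measured mass shift i | j biologically labelled
    carbons), from binomial natural 13C on the n-j unlabelled carbons."""
    a = np.zeros((n + 1, n + 1))
    for j in range(n + 1):
        for i in range(j, n + 1):
            k = i - j
            a[i, j] = comb(n - j, k) * p13c**k * (1 - p13c) ** (n - j - k)
    return a


def na_correct(mid: Sequence[float], p13c: float = 0.0107) -> np.ndarray:
    """Correct an MID for natural 13C abundance.

    Solves ``A x = mid`` by non-negative least squares, where A is the
    binomial convolution matrix for the metabolite's carbon count, then
    renormalises. With ``p13c = 0`` this is the identity. Only 13C is
    modelled (no 2H/15N/18O envelope).
    """
    if not 0.0 <= p13c < 1.0:
        raise ValueError("p13c must be in [0, 1)")
    mid = compute_mid(mid)
    if p13c == 0.0:
        return mid
    n = mid.size - 1
    x, _ = nnls(_na_matrix(n, p13c), mid)
    total = x.sum()
    if total == 0:
        raise ValueError("natural-abundance correction annihilated the MID")
    return x / total


def na_forward(mid: Sequence[float], p13c: float = 0.0107) -> np.ndarray:
    """Forward-convolve a tracer MID with natural 13C abundance (the
    inverse operation of :func:`na_correct`; used for round-trip checks)."""
    mid = compute_mid(mid)
    n = mid.size - 1
    return _na_matrix(n, p13c) @ mid


def na_correct_table(table: pd.DataFrame, p13c: float = 0.0107) -> pd.DataFrame:
    """Apply :func:`na_correct` per (sample, metabolite) of a tidy MID
    table (columns sample, metabolite, isotopologue, fraction)."""
    out = table.sort_values(["sample", "metabolite", "isotopologue"]).copy()
    corrected = np.empty(len(out))
    pos = 0
    for _, grp in out.groupby(["sample", "metabolite"], sort=False):
        vals = na_correct(grp["fraction"].values, p13c)
        corrected[pos:pos + len(vals)] = vals
        pos += len(vals)
    out["fraction"] = corrected
    return out


def fractional_contribution(mid: Sequence[float]) -> float:
    """FC = sum(i * M_i) / (n * sum(M_i)): the average fraction of heavy
    carbons in the pool; 0 for unlabelled, 1 for uniformly labelled."""
    mid = compute_mid(mid)
    n = mid.size - 1
    if n == 0:
        return 0.0
    i = np.arange(n + 1)
    return float((i * mid).sum() / n)


@dataclass(frozen=True)
class FluxRatioResult:
    metabolite: str
    numerator_shift: int
    denominator_shift: int
    value: float              # NaN when the denominator fraction ~ 0
    group: str | None = None

    @property
    def defined(self) -> bool:
        return bool(np.isfinite(self.value))


def flux_direction_ratio(
    mid: Sequence[float], metabolite: str, group: str | None = None
) -> FluxRatioResult:
    """Reductive-over-oxidative isotopologue ratio for one metabolite MID
    (citrate M+5/M+4, malate or aspartate M+3/M+4). A ratio of 1 means
    equal contribution from the oxidative and reductive routes; the value
    is NaN (flagged undefined) when the denominator fraction is ~ 0."""
    if metabolite not in RATIO_KINDS:
        raise KeyError(f"no flux-direction ratio defined for {metabolite!r}")
    num_i, den_i = RATIO_KINDS[metabolite]
    mid = compute_mid(mid)
    if mid.size <= max(num_i, den_i):
        raise ValueError(f"MID too short for M+{max(num_i, den_i)}")
    den = mid[den_i]
    value = np.nan if den < _ZERO_DENOM else float(mid[num_i] / den)
    return FluxRatioResult(metabolite=metabolite, numerator_shift=num_i,
                           denominator_shift=den_i, value=value, group=group)


def flux_ratio_table(table: pd.DataFrame) -> pd.DataFrame:
    """Flux-direction ratios for every (sample, ratio metabolite) of a
    tidy MID table; columns sample, group, metabolite, ratio."""
    rows = []
    for (sample, met), grp in table.groupby(["sample", "metabolite"]):
        if met not in RATIO_KINDS:
            continue
        mid = grp.sort_values("isotopologue")["fraction"].values
        res = flux_direction_ratio(mid, met)
        rows.append({"sample": sample,
                     "group": grp["group"].iloc[0] if "group" in grp else None,
                     "metabolite": met, "ratio": res.value})
    return pd.DataFrame(rows)


def estimate_reductive_fraction(ratio: float) -> float:
    """Invert the single-turn model: f_red = r / (1 + r)."""
    if not np.isfinite(ratio) or ratio < 0:
        return np.nan
    return ratio / (1.0 + ratio)


def compare_panels(
    data: pd.DataFrame,
    value_col: str,
    group_col: str = "group",
    by: str | None = "metabolite",
    normality_alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-metabolite group comparison with a Shapiro-Wilk normality gate.

    For each family member: if every group (n >= 3) passes Shapiro-Wilk at
    ``normality_alpha``, a parametric test is used (Welch t for 2 groups,
    one-way ANOVA otherwise); else a rank test (Mann-Whitney / Kruskal-
    Wallis). Raw p-values are reported without post hoc correction, the
    convention for the Kruskal-Wallis metabolite panels.
    """
    keys = data[by].unique() if by is not None else [None]
    rows = []
    for key in keys:
        sub = data if key is None else data[data[by] == key]
        names = [g for g in pd.unique(sub[group_col]) if pd.notna(g)]
        if len(names) < 2:
            continue
        samples = [sub.loc[sub[group_col] == g, value_col].dropna().values
                   for g in names]
        if any(len(s) < 2 for s in samples):
            rows.append({by or "family": key, "test": None, "p_raw": np.nan})
            continue
        normal = all(
            len(s) >= 3 and np.ptp(s) > 0
            and stats.shapiro(s).pvalue >= normality_alpha
            for s in samples)
        if normal:
            if len(samples) == 2:
                test, res = "welch_t", stats.ttest_ind(*samples, equal_var=False)
            else:
                test, res = "anova", stats.f_oneway(*samples)
            pval = float(res.pvalue)
        else:
            if len(samples) == 2:
                test = "mann_whitney"
                pval = float(stats.mannwhitneyu(
                    *samples, alternative="two-sided").pvalue)
            else:
                test = "kruskal"
                try:
                    pval = float(stats.kruskal(*samples).pvalue)
                except ValueError:
                    pval = 1.0
        rows.append({by or "family": key, "test": test, "p_raw": pval,
                     "n_per_group": tuple(len(s) for s in samples)})
    return pd.DataFrame(rows)
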