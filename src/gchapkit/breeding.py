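"""Breeding-signature tests: landrace (LAN) vs modern variety (MV) contrasts.

For one locus and two variety groups the comparison reports the change in
Shannon evenness ΔE_H with a Z test (bootstrap standard errors), the change
in haplotype counts, the number of new gcHaps present in the modern group
but absent from the landraces, and the drift of the dominant haplotype's
frequency F(P) with a 2x2 Pearson chi-square (no continuity correction).
The artificial-selection label is "up" for ΔE_H > 0 (diversity gained under
breeding), "down" for ΔE_H < 0.

There is no closed-form variance for the evenness of haplotype counts, so
SE(E_H) comes from a seeded multinomial bootstrap of varieties within each
group; a Hutcheson-style analytic variance is provided for cross-checking.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .calling import GcHapTable, frequency_vector
from .diversity import evenness_from_counts, shannon_evenness

logger = logging.getLogger(__name__)

MIN_GROUP_SIZE = 10


@dataclass
class BreedingComparison:
    gene_id: str
    group_a: str
    group_b: str
    n_a: int
    n_b: int
    e_h_a: float
    e_h_b: float
    delta_e_h: float
    gchap_n_a: int
    gchap_n_b: int
    delta_gchap_n: int
    n_new_gchaps: int
    f_p_a: float
    f_p_b: float
    dominant_hap: str
    z_stat: float
    z_pvalue: float
    chi2_stat: float
    chi2_pvalue: float
    selection_effect: str
    significance: str

    def as_row(self) -> dict:
        return {
            "gene_id": self.gene_id, "group_A": self.group_a,
            "group_B": self.group_b, "n_A": self.n_a, "n_B": self.n_b,
            "E_H_A": self.e_h_a, "E_H_B": self.e_h_b,
            "delta_E_H": self.delta_e_h,
            "gcHapN_A": self.gchap_n_a, "gcHapN_B": self.gchap_n_b,
            "delta_gcHapN": self.delta_gchap_n,
            "n_new_gcHaps": self.n_new_gchaps,
            "F_P_A": self.f_p_a, "F_P_B": self.f_p_b,
            "dominant_hap": self.dominant_hap,
            "Z": self.z_stat, "Z_p": self.z_pvalue,
            "chi2": self.chi2_stat, "chi2_p": self.chi2_pvalue,
            "selection_effect": self.selection_effect,
            "significance": self.significance,
        }


def selection_effect_label(delta_e_h: float) -> str:
    """Artificial-selection label from the evenness change."""
    if not math.isfinite(delta_e_h):
        raise ValueError("delta E_H must be finite")
    if delta_e_h > 0:
        return "up"
    if delta_e_h < 0:
        return "down"
    return "none"


def significance_stars(p: float) -> str:
    if not math.isfinite(p):
        return "na"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def frequency_drift_test(
    carriers_a: int, n_a: int, carriers_b: int, n_b: int
) -> tuple[float, float]:
    """Pearson chi-square (df=1, no continuity correction) on carriers vs not.

    Returns (nan, nan) when any margin of the 2x2 table is zero (the test
    is undefined and the caller should flag the comparison).
    """
    if min(carriers_a, carriers_b, n_a, n_b) < 0:
        raise ValueError("counts must be non-negative")
    if carriers_a > n_a or carriers_b > n_b:
        raise ValueError("carriers cannot exceed group size")
    table = np.array([
        [carriers_a, n_a - carriers_a],
        [carriers_b, n_b - carriers_b],
    ])
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        return float("nan"), float("nan")
    res = stats.chi2_contingency(table, correction=False)
    return float(res.statistic), float(res.pvalue)


def bootstrap_evenness_se(
    counts: np.ndarray, n_boot: int, rng: np.random.Generator
) -> float:
    """Bootstrap SE of E_H: resample varieties (multinomial on observed counts)."""
    counts = np.asarray(counts, dtype=int)
    n = counts.sum()
    resampled = rng.multinomial(n, counts / n, size=n_boot)
    return float(np.std(evenness_from_counts(resampled), ddof=1))


def evenness_se_analytic(counts: np.ndarray) -> float:
    """Hutcheson-style delta-method SE of E_H, for cross-checking the bootstrap."""
    counts = np.asarray(counts, dtype=float)
    n = counts.sum()
    p = counts[counts > 0] / n
    if p.size <= 1:
        return 0.0
    var_h = (np.sum(p * np.log(p) ** 2) - np.sum(p * np.log(p)) ** 2) / n
    return float(np.sqrt(max(var_h, 0.0)) / np.log(p.size))


def compare_groups(
    table: GcHapTable,
    group_a: list[str],
    group_b: list[str],
    label_a: str = "A",
    label_b: str = "B",
    n_boot: int = 1000,
    seed: int = 0,
) -> BreedingComparison:
    """Full LAN-vs-MV style comparison of two variety groups at one locus."""
    if n_boot < 200:
        raise ValueError("n_boot must be >= 200 for a stable bootstrap SE")
    fv_a = frequency_vector(table, group_a, label_a)
    fv_b = frequency_vector(table, group_b, label_b)
    counts_a = np.array(list(fv_a.counts.values()))
    counts_b = np.array(list(fv_b.counts.values()))
    n_a, n_b = int(counts_a.sum()), int(counts_b.sum())
    e_h_a = shannon_evenness(fv_a)
    e_h_b = shannon_evenness(fv_b)
    delta = e_h_b - e_h_a
    if n_a < MIN_GROUP_SIZE or n_b < MIN_GROUP_SIZE:
        logger.warning(
            "%s: group below %d varieties; Z reported as undefined",
            table.gene_id, MIN_GROUP_SIZE,
        )
        z = z_p = float("nan")
    else:
        rng = np.random.default_rng(seed)
        se_a = bootstrap_evenness_se(counts_a, n_boot, rng)
        se_b = bootstrap_evenness_se(counts_b, n_boot, rng)
        denom = math.hypot(se_a, se_b)
        if denom == 0.0:
            z = 0.0 if delta == 0.0 else math.copysign(math.inf, delta)
            z_p = 1.0 if delta == 0.0 else 0.0
        else:
            z = delta / denom
            z_p = 2.0 * stats.norm.sf(abs(z))
    haps_a, haps_b = set(fv_a.freqs), set(fv_b.freqs)
    new_haps = len(haps_b - haps_a)
    # dominant hap of group A (the ancestral group) tracked for F(P) drift
    dominant = max(fv_a.freqs, key=lambda h: (fv_a.freqs[h], h))
    f_p_a = fv_a.freqs[dominant]
    f_p_b = fv_b.freqs.get(dominant, 0.0)
    chi2, chi2_p = frequency_drift_test(
        fv_a.counts[dominant], n_a, fv_b.counts.get(dominant, 0), n_b
    )
    return BreedingComparison(
        gene_id=table.gene_id, group_a=label_a, group_b=label_b,
        n_a=n_a, n_b=n_b,
        e_h_a=e_h_a, e_h_b=e_h_b, delta_e_h=delta,
        gchap_n_a=len(haps_a), gchap_n_b=len(haps_b),
        delta_gchap_n=len(haps_b) - len(haps_a),
        n_new_gchaps=new_haps,
        f_p_a=f_p_a, f_p_b=f_p_b, dominant_hap=dominant,
        z_stat=z, z_pvalue=z_p,
        chi2_stat=chi2, chi2_pvalue=chi2_p,
        selection_effect=selection_effect_label(delta),
        significance=significance_stars(z_p),
    )


def breeding_table(comparisons: list[BreedingComparison]):
    """Tabular layout mirroring the LAN/MV comparison tables."""
    import pandas as pd

    return pd.DataFrame([c.as_row() for c in comparisons])
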