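"""Haplotype-trait association: favorable/unfavorable contrasts and ANOVA.

Per locus, the favorable gcHap is the most frequent major haplotype (the
dominant one, presumed favored by selection) and the unfavorable gcHap is
the lowest-frequency major haplotype; their trait values are contrasted
with a Welch two-sample test per trait.  Across all major haplotypes, a
one-way fixed-effects ANOVA with Tukey HSD pairwise comparisons yields a
compact letter display (haps sharing a letter are not significantly
different at alpha); associations with p < 1e-7 are flagged as very
significant.  No multiple-testing correction is applied to the flags (a
Bonferroni column is emitted for transparency only).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .calling import GcHapTable, classify_major_gchaps, frequency_vector
from .io import PhenotypeTable

VERY_SIGNIFICANT = 1e-7

#: default trait direction map for the yield-trait favorable-allele scan
DEFAULT_DIRECTIONS = {t: "higher" for t in ("TGW", "GL", "GW", "PL", "CN")}


@dataclass
class AssociationResult:
    gene_id: str
    trait: str
    groups: dict[str, dict]          # hap_id -> {n, mean, sd}
    f_stat: float
    anova_pvalue: float
    tukey_pvalues: dict[tuple[str, str], float]
    letters: dict[str, str]
    dropped: list[str] = field(default_factory=list)
    very_significant: bool = False


@dataclass
class TraitContrast:
    trait: str
    mean_favorable: float
    mean_unfavorable: float
    difference: float
    pvalue: float
    significant: bool
    status: str = "ok"               # "ok" | "insufficient data"


@dataclass
class FavorablePair:
    gene_id: str
    favorable_hap: str
    unfavorable_hap: str
    favorable_freq: float
    unfavorable_freq: float
    contrasts: dict[str, TraitContrast] = field(default_factory=dict)


def label_favorable_unfavorable(
    table: GcHapTable, subset: list[str], threshold: float = 0.01
) -> FavorablePair:
    """Pick the favorable (rank-1 major) and unfavorable (rarest major) haps."""
    majors = classify_major_gchaps(table, subset, threshold)
    if len(majors) < 2:
        raise ValueError(
            f"{table.gene_id}: fewer than 2 major gcHaps; contrast undefined"
        )
    fv = frequency_vector(table, subset)
    rank = {h: i for i, h in enumerate(table.hap_ids)}
    favorable = max(majors, key=lambda h: (fv.freqs[h], -rank[h]))
    # ties resolved away from the favorable pick so the pair is distinct
    unfavorable = min(majors, key=lambda h: (fv.freqs[h], -rank[h]))
    return FavorablePair(
        gene_id=table.gene_id,
        favorable_hap=favorable,
        unfavorable_hap=unfavorable,
        favorable_freq=fv.freqs[favorable],
        unfavorable_freq=fv.freqs[unfavorable],
    )


def contrast_traits(
    pair: FavorablePair,
    table: GcHapTable,
    phenotypes: PhenotypeTable,
    traits: list[str] | None = None,
    alpha: float = 0.05,
    min_n: int = 5,
) -> FavorablePair:
    """Welch two-sample contrast of favorable vs unfavorable carriers per trait."""
    carriers_f = table.carriers(pair.favorable_hap)
    carriers_u = table.carriers(pair.unfavorable_hap)
    for trait in traits or phenotypes.trait_codes:
        x = phenotypes.values(trait, carriers_f)
        y = phenotypes.values(trait, carriers_u)
        if len(x) < min_n or len(y) < min_n:
            pair.contrasts[trait] = TraitContrast(
                trait, float("nan"), float("nan"), float("nan"),
                float("nan"), False, status="insufficient data",
            )
            continue
        if np.allclose(x, x.iloc[0]) and np.allclose(y, x.iloc[0]):
            diff, p = 0.0, 1.0
        else:
            res = stats.ttest_ind(x, y, equal_var=False)
            diff, p = float(x.mean() - y.mean()), float(res.pvalue)
        pair.contrasts[trait] = TraitContrast(
            trait, float(x.mean()), float(y.mean()), diff, p, p < alpha
        )
    return pair


def compact_letter_display(
    group_ids: list[str],
    means: dict[str, float],
    pairwise_p: dict[tuple[str, str], float],
    alpha: float = 0.05,
) -> dict[str, str]:
    """Letters such that two groups share a letter iff not significantly different.

    Letters are the maximal cliques of the graph whose edges join
    non-significant pairs; cliques are lettered in order of their best
    (highest) group mean.  Exact for the small group counts used here.
    """
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(group_ids)
    for (a, b), p in pairwise_p.items():
        if p >= alpha:
            g.add_edge(a, b)
    cliques = list(nx.find_cliques(g))
    cliques.sort(key=lambda c: (-max(means[m] for m in c), sorted(c)))
    letters = {gid: "" for gid in group_ids}
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    for letter, clique in zip(alphabet, cliques):
        for gid in clique:
            letters[gid] += letter
    return letters


def anova_f_brute(groups: list[np.ndarray]) -> tuple[float, float]:
    """One-way ANOVA F from explicit sums of squares (independent oracle)."""
    all_values = np.concatenate(groups)
    grand = all_values.mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df_b = len(groups) - 1
    df_w = len(all_values) - len(groups)
    f = (ss_between / df_b) / (ss_within / df_w)
    return float(f), float(stats.f.sf(f, df_b, df_w))


def gchap_trait_anova(
    table: GcHapTable,
    phenotypes: PhenotypeTable,
    trait: str,
    subset: list[str] | None = None,
    major_threshold: float = 0.01,
    min_n: int = 5,
    alpha: float = 0.05,
) -> AssociationResult:
    """One-way ANOVA of a trait across major gcHaps, with Tukey HSD letters."""
    subset = subset or list(table.assignments)
    majors = classify_major_gchaps(table, subset, major_threshold)
    members = set(subset)
    values: dict[str, pd.Series] = {}
    dropped = []
    for hap in majors:
        carriers = [v for v in table.carriers(hap) if v in members]
        x = phenotypes.values(trait, carriers)
        if len(x) < min_n:
            dropped.append(hap)
        else:
            values[hap] = x
    if len(values) < 2:
        raise ValueError(
            f"{table.gene_id}/{trait}: fewer than 2 major gcHaps with >= "
            f"{min_n} phenotyped carriers"
        )
    haps = list(values)
    arrays = [values[h].to_numpy() for h in haps]
    if all(np.ptp(a) == 0 for a in arrays) and len({a[0] for a in arrays}) == 1:
        f_stat, p = 0.0, 1.0
        tukey_p = {pair: 1.0 for pair in itertools.combinations(haps, 2)}
    else:
        f_stat, p = stats.f_oneway(*arrays)
        f_stat, p = float(f_stat), float(p)
        tukey = stats.tukey_hsd(*arrays)
        tukey_p = {
            (haps[i], haps[j]): float(tukey.pvalue[i, j])
            for i, j in itertools.combinations(range(len(haps)), 2)
        }
    means = {h: float(values[h].mean()) for h in haps}
    letters = compact_letter_display(haps, means, tukey_p, alpha)
    return AssociationResult(
        gene_id=table.gene_id,
        trait=trait,
        groups={
            h: {"n": int(len(values[h])), "mean": means[h],
                "sd": float(values[h].std(ddof=1))}
            for h in haps
        },
        f_stat=f_stat,
        anova_pvalue=p,
        tukey_pvalues=tukey_p,
        letters=letters,
        dropped=dropped,
        very_significant=p < VERY_SIGNIFICANT,
    )


def association_table(results: list[AssociationResult]) -> pd.DataFrame:
    """Tabular association summary with a Bonferroni column (transparency only)."""
    rows = []
    m = len(results)
    for r in results:
        rows.append({
            "gene_id": r.gene_id, "trait": r.trait,
            "F": r.f_stat, "p": r.anova_pvalue,
            "p_bonferroni": min(1.0, r.anova_pvalue * m),
            "very_significant": r.very_significant,
            "letters": ";".join(f"{h}={l}" for h, l in r.letters.items()),
        })
    return pd.DataFrame(rows)


def favorable_allele_frequencies(
    table: GcHapTable,
    panel,
    result: AssociationResult,
    direction: str,
) -> pd.DataFrame:
    """Frequency of the trait-favorable hap per subpopulation and aggregate.

    The trait-favorable hap is the analysed major hap with the best mean in
    the stated direction ("higher" or "lower").  Rows report subpopulations
    plus Xian/Geng population aggregates, with carrier counts.
    """
    if direction not in ("higher", "lower"):
        raise ValueError(f"trait direction must be 'higher' or 'lower', got "
                         f"{direction!r}")
    sign = 1 if direction == "higher" else -1
    best = max(result.groups, key=lambda h: sign * result.groups[h]["mean"])
    rows = []

    def _row(label: str, members: list[str]) -> dict:
        members = [v for v in members if v in table.assignments]
        carriers = sum(1 for v in members if table.assignments[v] == best)
        return {
            "gene_id": table.gene_id, "trait": result.trait,
            "favorable_hap": best, "group": label,
            "n_accession": carriers,
            "frequency": carriers / len(members) if members else 0.0,
        }

    for subpop in panel.subpopulations():
        if subpop:
            rows.append(_row(subpop, panel.members(subpopulation=subpop)))
    for pop in panel.populations():
        rows.append(_row(pop, panel.members(population=pop)))
    rows.append(_row("ALL", panel.variety_ids))
    return pd.DataFrame(rows)
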