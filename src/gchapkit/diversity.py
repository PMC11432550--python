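"""Per-locus haplotype diversity and population differentiation.

Diversity of a gene-CDS-haplotype (gcHap) frequency vector is summarised by
Shannon's evenness E_H, the normalised Shannon entropy

    E_H = -sum_i p_i ln p_i / ln N,

where N is the number of haplotypes observed (p_i > 0) in the population at
the locus.  E_H is 1 when all observed haplotypes are equally frequent and is
defined as 0 for a monomorphic locus (N = 1).  Differentiation between two
populations is Nei's genetic identity

    I = sum_i x_i y_i / sqrt(sum_i x_i^2 * sum_i y_i^2),

the cosine similarity of the two haplotype frequency vectors expressed over
the union of haplotypes; I = 1 for identical composition and values below a
reporting threshold (0.35 by convention here) are flagged as strong
differentiation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .calling import GcHapTable, FrequencyVector, frequency_vector

logger = logging.getLogger(__name__)

DIFFERENTIATION_THRESHOLD = 0.35


@dataclass
class DiversityRecord:
    """Diversity summary for one gene in one population."""

    gene_id: str
    population: str
    n_varieties: int
    gchap_n: int
    major_gchap_n: int
    e_h: float
    dominant_hap: str
    f_p: float


@dataclass
class DifferentiationMatrix:
    """Pairwise Nei identity between populations at one locus."""

    gene_id: str
    populations: list[str]
    identity: pd.DataFrame
    threshold: float = DIFFERENTIATION_THRESHOLD
    flagged: list[tuple[str, str]] = field(default_factory=list)


def shannon_evenness(freqs) -> float:
    """Shannon's evenness E_H of a haplotype frequency vector.

    ``freqs`` is a :class:`FrequencyVector` or any sequence of non-negative
    frequencies.  Zero entries are ignored (0 ln 0 := 0); a vector with a
    single observed haplotype has E_H = 0 by convention.
    """
    if isinstance(freqs, FrequencyVector):
        p = np.asarray(list(freqs.freqs.values()), dtype=float)
    else:
        p = np.asarray(freqs, dtype=float)
    if np.any(p < 0):
        raise ValueError("negative frequency in evenness input")
    p = p[p > 0]
    n = p.size
    if n == 0:
        raise ValueError("empty frequency vector")
    if n == 1:
        return 0.0
    h = -float(np.sum(p * np.log(p)))
    return h / np.log(n)


def evenness_from_counts(counts: np.ndarray) -> np.ndarray:
    """Vectorised E_H over rows of a haplotype count matrix.

    Used by the bootstrap in :mod:`gchapkit.breeding`; each row is one
    resample's haplotype counts.
    """
    counts = np.atleast_2d(np.asarray(counts, dtype=float))
    totals = counts.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = counts / totals
        plogp = np.where(p > 0, p * np.log(p), 0.0)
    h = -plogp.sum(axis=1)
    n_obs = (counts > 0).sum(axis=1)
    out = np.zeros(counts.shape[0])
    multi = n_obs > 1
    out[multi] = h[multi] / np.log(n_obs[multi])
    return out


def nei_identity(x, y) -> float:
    """Nei's genetic identity between two frequency vectors.

    :class:`FrequencyVector` inputs are aligned over the union of their
    haplotype ids (a haplotype absent from one population contributes 0);
    plain sequences are assumed already aligned.
    """
    if isinstance(x, FrequencyVector) and isinstance(y, FrequencyVector):
        haps = sorted(set(x.freqs) | set(y.freqs))
        xv = np.array([x.freqs.get(h, 0.0) for h in haps])
        yv = np.array([y.freqs.get(h, 0.0) for h in haps])
    else:
        xv = np.asarray(x, dtype=float)
        yv = np.asarray(y, dtype=float)
        if xv.shape != yv.shape:
            raise ValueError("frequency vectors must share support")
    sx = float(np.dot(xv, xv))
    sy = float(np.dot(yv, yv))
    if sx == 0.0 or sy == 0.0:
        raise ValueError("all-zero frequency vector in Nei identity")
    return float(np.dot(xv, yv) / np.sqrt(sx * sy))


def diversity_record(
    table: GcHapTable,
    subset: list[str],
    population: str,
    major_threshold: float = 0.01,
) -> DiversityRecord:
    """Build the :class:`DiversityRecord` for one population subset."""
    fv = frequency_vector(table, subset, population=population)
    n = sum(fv.counts.values())
    freqs = fv.freqs
    gchap_n = len(freqs)
    major_n = sum(1 for p in freqs.values() if p >= major_threshold)
    # dominant hap: max frequency, ties broken by hap rank (Hap1 < Hap2 < ...)
    dominant = max(freqs, key=lambda h: (freqs[h], -_hap_rank(h)))
    return DiversityRecord(
        gene_id=table.gene_id,
        population=population,
        n_varieties=n,
        gchap_n=gchap_n,
        major_gchap_n=major_n,
        e_h=shannon_evenness(fv),
        dominant_hap=dominant,
        f_p=freqs[dominant],
    )


def _hap_rank(hap_id: str) -> int:
    try:
        return int(hap_id.replace("Hap", ""))
    except ValueError:
        return 10**9


def diversity_summary(
    table: GcHapTable,
    panel,
    populations: list[str] | None = None,
    major_threshold: float = 0.01,
) -> list[DiversityRecord]:
    """One DiversityRecord per (gene, population) plus a whole-panel record.

    Populations left empty after exclusions are skipped with a warning
    rather than raising.
    """
    from .io import VarietyPanel  # local import to avoid cycle at import time

    assert isinstance(panel, VarietyPanel)
    if populations is None:
        populations = list(panel.populations())
    records = []
    assigned = set(table.assignments)
    for pop in populations:
        members = [v for v in panel.members(population=pop) if v in assigned]
        if not members:
            logger.warning(
                "population %s empty after exclusions at %s; record skipped",
                pop, table.gene_id,
            )
            continue
        records.append(diversity_record(table, members, pop, major_threshold))
    whole = [v for v in panel.variety_ids if v in assigned]
    records.append(diversity_record(table, whole, "ALL", major_threshold))
    return records


def pairwise_differentiation(
    table: GcHapTable,
    panel,
    populations: list[str] | None = None,
    threshold: float = DIFFERENTIATION_THRESHOLD,
) -> DifferentiationMatrix:
    """Symmetric Nei-identity matrix across populations at one locus.

    Pairs with I below ``threshold`` are flagged as strongly differentiated.
    """
    if populations is None:
        populations = list(panel.populations())
    if len(populations) < 2:
        raise ValueError("pairwise differentiation needs >= 2 populations")
    assigned = set(table.assignments)
    vectors = {}
    for pop in populations:
        members = [v for v in panel.members(population=pop) if v in assigned]
        if not members:
            raise ValueError(f"population {pop!r} absent or empty at {table.gene_id}")
        vectors[pop] = frequency_vector(table, members, population=pop)
    mat = pd.DataFrame(
        np.eye(len(populations)), index=populations, columns=populations
    )
    flagged = []
    for i, a in enumerate(populations):
        for b in populations[i + 1:]:
            val = nei_identity(vectors[a], vectors[b])
            mat.loc[a, b] = mat.loc[b, a] = val
            if val < threshold:
                flagged.append((a, b))
    return DifferentiationMatrix(
        gene_id=table.gene_id,
        populations=list(populations),
        identity=mat,
        threshold=threshold,
        flagged=flagged,
    )


def diversity_table(records: list[DiversityRecord]) -> pd.DataFrame:
    """Tabular layout of diversity records (one row per gene x population)."""
    return pd.DataFrame(
        [
            {
                "gene_id": r.gene_id,
                "population": r.population,
                "n_varieties": r.n_varieties,
                "gcHapN": r.gchap_n,
                "major_gcHapN": r.major_gchap_n,
                "E_H": r.e_h,
                "dominant_hap": r.dominant_hap,
                "F_P": r.f_p,
            }
            for r in records
        ]
    )
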