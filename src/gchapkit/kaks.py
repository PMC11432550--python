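"""Nei–Gojobori (1986) Ka/Ks for codon-aligned CDS pairs.

Synonymous and non-synonymous sites are counted per codon as the fraction
of the three possible single-base changes at each position that preserve
the encoded amino acid, with changes to stop codons excluded from the
denominator.  Differences between codons differing at several positions
are resolved by averaging the synonymous/non-synonymous split over all
minimal substitution pathways (pathways passing through a stop codon are
discarded).  Proportions are Jukes–Cantor corrected:

    Ks = -3/4 ln(1 - 4 pS / 3),   Ka analogously,

undefined (flagged) when the proportion reaches the 0.75 singularity.
A Ka/Ks ratio below 1 is annotated as purifying selection, 1 as neutral,
above 1 as positive selection.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

from Bio.Data.CodonTable import unambiguous_dna_by_id

_TABLE = unambiguous_dna_by_id[1]
CODON_TO_AA = dict(_TABLE.forward_table)
STOP_CODONS = set(_TABLE.stop_codons)
BASES = "ACGT"


@dataclass
class KaKsResult:
    seq_a: str
    seq_b: str
    s_sites: float
    n_sites: float
    sd: float
    nd: float
    ps: float
    pn: float
    ks: float
    ka: float
    ratio: float
    selection: str

    def as_row(self) -> dict:
        return {
            "seq_a": self.seq_a, "seq_b": self.seq_b,
            "S": self.s_sites, "N": self.n_sites,
            "Sd": self.sd, "Nd": self.nd,
            "pS": self.ps, "pN": self.pn,
            "Ks": self.ks, "Ka": self.ka,
            "Ka/Ks": self.ratio, "selection": self.selection,
        }


def _check_codon(codon: str) -> str:
    codon = codon.upper()
    if len(codon) != 3 or any(b not in BASES for b in codon):
        raise ValueError(f"ambiguous or malformed codon {codon!r}")
    if codon in STOP_CODONS:
        raise ValueError(f"stop codon {codon!r} not allowed")
    return codon


def ng86_site_counts(codon: str) -> tuple[float, float]:
    """Synonymous and non-synonymous site counts of one codon.

    Each position contributes the fraction of its possible single-base
    changes that are synonymous; changes producing a stop codon are
    excluded from the denominator.  The two counts sum to 3 per codon.
    """
    codon = _check_codon(codon)
    aa = CODON_TO_AA[codon]
    syn_sites = 0.0
    for i in range(3):
        syn = valid = 0
        for b in BASES:
            if b == codon[i]:
                continue
            mutant = codon[:i] + b + codon[i + 1:]
            if mutant in STOP_CODONS:
                continue
            valid += 1
            if CODON_TO_AA[mutant] == aa:
                syn += 1
        syn_sites += syn / valid if valid else 0.0
    return syn_sites, 3.0 - syn_sites


def codon_differences(codon_a: str, codon_b: str) -> tuple[float, float]:
    """Average (synonymous, non-synonymous) differences between two codons.

    All minimal substitution pathways (orders of the differing positions)
    are enumerated; pathways crossing a stop codon are discarded unless
    every pathway does.
    """
    codon_a = _check_codon(codon_a)
    codon_b = _check_codon(codon_b)
    diff_pos = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff_pos:
        return 0.0, 0.0
    pathways = []
    for order in itertools.permutations(diff_pos):
        current = codon_a
        sd = nd = 0
        blocked = False
        for i in order:
            nxt = current[:i] + codon_b[i] + current[i + 1:]
            if nxt in STOP_CODONS:
                blocked = True
                break
            if CODON_TO_AA[current] == CODON_TO_AA[nxt]:
                sd += 1
            else:
                nd += 1
            current = nxt
        if not blocked:
            pathways.append((sd, nd))
    if not pathways:
        # all pathways cross a stop: fall back to counting every change as
        # non-synonymous (degenerate case, effectively unreachable in CDS data)
        return 0.0, float(len(diff_pos))
    sd = sum(p[0] for p in pathways) / len(pathways)
    nd = sum(p[1] for p in pathways) / len(pathways)
    return sd, nd


def _jukes_cantor(p: float) -> float:
    if p >= 0.75:
        return math.nan
    if p == 0.0:
        return 0.0
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


def kaks_ng86(cds_a: str, cds_b: str, id_a: str = "seq_a",
              id_b: str = "seq_b") -> KaKsResult:
    """NG86 Ka/Ks with Jukes–Cantor correction for a codon-aligned pair.

    Site counts are averaged between the two sequences.  The ratio is NaN
    when Ks = 0 (no synonymous divergence) and the correction is flagged
    NaN past its 0.75 singularity.
    """
    cds_a, cds_b = cds_a.upper(), cds_b.upper()
    if len(cds_a) != len(cds_b):
        raise ValueError("sequences must be codon-aligned to equal length")
    if len(cds_a) % 3:
        raise ValueError("sequence length not divisible by 3")
    s_a = n_a = s_b = n_b = sd = nd = 0.0
    for i in range(0, len(cds_a), 3):
        ca, cb = cds_a[i:i + 3], cds_b[i:i + 3]
        sa, na = ng86_site_counts(ca)
        sb, nb = ng86_site_counts(cb)
        s_a += sa; n_a += na; s_b += sb; n_b += nb
        dsd, dnd = codon_differences(ca, cb)
        sd += dsd; nd += dnd
    s_sites = (s_a + s_b) / 2.0
    n_sites = (n_a + n_b) / 2.0
    ps = sd / s_sites if s_sites else 0.0
    pn = nd / n_sites if n_sites else 0.0
    ks = _jukes_cantor(ps)
    ka = _jukes_cantor(pn)
    if ks != ks or ks == 0.0:
        ratio = math.nan
        selection = "undefined"
    else:
        ratio = ka / ks
        if ratio < 1.0:
            selection = "purifying"
        elif ratio > 1.0:
            selection = "positive"
        else:
            selection = "neutral"
    return KaKsResult(id_a, id_b, s_sites, n_sites, sd, nd, ps, pn,
                      ks, ka, ratio, selection)


def annotate_hap_differences(cds_a: str, cds_b: str) -> list[dict]:
    """Codon-aware classification of the differences between two haplotypes.

    Reports, per differing codon, whether the change is synonymous or
    non-synonymous together with the amino-acid change.
    """
    if len(cds_a) != len(cds_b) or len(cds_a) % 3:
        raise ValueError("haplotype sequences must be codon-aligned")
    out = []
    for i in range(0, len(cds_a), 3):
        ca, cb = cds_a[i:i + 3].upper(), cds_b[i:i + 3].upper()
        if ca == cb:
            continue
        aa_a = CODON_TO_AA.get(ca, "*")
        aa_b = CODON_TO_AA.get(cb, "*")
        out.append({
            "codon_index": i // 3 + 1,
            "codon_a": ca, "codon_b": cb,
            "aa_a": aa_a, "aa_b": aa_b,
            "effect": "synonymous" if aa_a == aa_b else "non-synonymous",
        })
    return out
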