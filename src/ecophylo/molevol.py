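"""Nucleotide diversity and Nei-Gojobori (NG86) Ka/Ks for codon alignments.

Implements the counting-based dN/dS estimator of Nei & Gojobori (1986)
under the universal genetic code: per-codon synonymous site fractions
(number of synonymous one-step changes at a position divided by 3, summed
over the three positions), pathway averaging over all minimal substitution
paths between differing codons (paths through stop codons excluded), and
the Jukes-Cantor multiple-hit correction

    d = -(3/4) * ln(1 - (4/3) * p).

Gene-level summaries apply the standard plastid-gene filters: pseudogenes
and alignments shorter than 300 bp are excluded.  Gaps and ambiguous bases
are handled by pairwise deletion (positions or codons containing '-'/'N'
in either sequence of a pair are dropped for that pair), matching the
default behaviour of pairwise statistics in DnaSP.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from Bio.Data.CodonTable import unambiguous_dna_by_id

__all__ = [
    "CodonAlignment",
    "DiversityResult",
    "KaKsResult",
    "SENSE_CODONS",
    "STOP_CODONS",
    "GENETIC_CODE",
    "synonymous_sites",
    "jukes_cantor",
    "nucleotide_diversity",
    "nei_gojobori_pair",
    "gene_kaks_summary",
]

_BASES = "ACGT"
_TABLE = unambiguous_dna_by_id[1]  # universal code
GENETIC_CODE: dict[str, str] = dict(_TABLE.forward_table)
STOP_CODONS: frozenset[str] = frozenset(_TABLE.stop_codons)
SENSE_CODONS: tuple[str, ...] = tuple(sorted(GENETIC_CODE))

_PURINES = {"A", "G"}


def is_transition(a: str, b: str) -> bool:
    """A<->G or C<->T substitution."""
    return a != b and ((a in _PURINES) == (b in _PURINES))


def synonymous_sites(codon: str) -> float:
    """NG86 synonymous site count of a sense codon.

    Each position contributes (synonymous one-step changes)/3; changes to
    stop codons are not synonymous, so the nonsynonymous count is always
    ``3 - synonymous_sites(codon)``.
    """
    aa = GENETIC_CODE[codon]
    s = 0.0
    for pos in range(3):
        for base in _BASES:
            if base == codon[pos]:
                continue
            alt = codon[:pos] + base + codon[pos + 1:]
            if alt not in STOP_CODONS and GENETIC_CODE[alt] == aa:
                s += 1.0 / 3.0
    return s


_SYN_SITES: dict[str, float] = {c: synonymous_sites(c) for c in SENSE_CODONS}


def _pathway_counts(c1: str, c2: str) -> tuple[float, float, bool]:
    """Pathway-averaged (synonymous, nonsynonymous) difference counts.

    Enumerates every ordering of the differing positions, walks each path
    one substitution at a time, and drops paths that pass through a stop
    codon.  Returns ``(sd, nd, ok)``; ``ok`` is False when every pathway is
    blocked by a stop codon (the codon pair then carries no information).
    """
    diff = [i for i in range(3) if c1[i] != c2[i]]
    if not diff:
        return 0.0, 0.0, True
    sd_total = nd_total = 0.0
    n_paths = 0
    for order in itertools.permutations(diff):
        cur = c1
        sd = nd = 0.0
        blocked = False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            if nxt in STOP_CODONS:
                blocked = True
                break
            if GENETIC_CODE[cur] == GENETIC_CODE[nxt]:
                sd += 1.0
            else:
                nd += 1.0
            cur = nxt
        if not blocked:
            sd_total += sd
            nd_total += nd
            n_paths += 1
    if n_paths == 0:
        return 0.0, 0.0, False
    return sd_total / n_paths, nd_total / n_paths, True


_PAIR_CACHE: dict[tuple[str, str], tuple[float, float, bool]] = {}


def _pair_diff(c1: str, c2: str) -> tuple[float, float, bool]:
    key = (c1, c2) if c1 <= c2 else (c2, c1)
    hit = _PAIR_CACHE.get(key)
    if hit is None:
        hit = _pathway_counts(*key)
        _PAIR_CACHE[key] = hit
    return hit


def jukes_cantor(p: float) -> float | None:
    """JC69 distance ``-(3/4) ln(1 - 4p/3)``; None outside the domain."""
    if p < 0:
        raise ValueError("proportion of differences must be >= 0")
    if p >= 0.75:
        return None
    return float(max(-0.75 * np.log(1.0 - p / 0.75), 0.0))


# --------------------------------------------------------------------- types

@dataclass
class CodonAlignment:
    """In-frame codon alignment for one gene."""

    gene: str
    records: list[tuple[str, str]]  # (label, nucleotide string)
    pseudogene: bool = False

    def __post_init__(self) -> None:
        if not self.records:
            raise ValueError(f"{self.gene}: empty alignment")
        lengths = {len(seq) for _, seq in self.records}
        if len(lengths) != 1:
            raise ValueError(f"{self.gene}: unequal sequence lengths {sorted(lengths)}")
        (self.length,) = lengths
        if self.length % 3:
            raise ValueError(f"{self.gene}: length {self.length} not divisible by 3")
        ok = set("ACGT-N")
        for lab, seq in self.records:
            extra = set(seq.upper()) - ok
            if extra:
                raise ValueError(f"{self.gene}/{lab}: invalid characters {sorted(extra)}")

    @property
    def labels(self) -> list[str]:
        return [lab for lab, _ in self.records]


@dataclass
class DiversityResult:
    gene: str
    pi: float
    sites_used: float  # mean number of compared sites per pair
    pairs_used: int


@dataclass
class KaKsResult:
    gene: str
    s_sites: float  # mean synonymous sites
    n_sites: float  # mean nonsynonymous sites
    ka: float | None
    ks: float | None
    ratio: float | None
    selection_class: str  # positive | neutral | purifying | undefined
    codons_compared: int = 0
    codons_skipped: int = 0  # gap/N codons plus all-pathways-blocked pairs
    excluded_reason: str | None = None


def _classify(ratio: float | None, tol: float = 1e-6) -> str:
    if ratio is None:
        return "undefined"
    if abs(ratio - 1.0) <= tol:
        return "neutral"
    return "positive" if ratio > 1.0 else "purifying"


# ---------------------------------------------------------------- diversity

def nucleotide_diversity(aln: CodonAlignment) -> DiversityResult:
    """Average pairwise proportion of differing sites (pi).

    Positions with '-' or 'N' in either member of a pair are excluded for
    that pair (pairwise deletion); pairs with no comparable site are
    skipped.  Fails if every pair is skipped.
    """
    seqs = [seq.upper() for _, seq in aln.records]
    if len(seqs) < 2:
        raise ValueError(f"{aln.gene}: need >= 2 sequences for pi")
    arrs = [np.frombuffer(s.encode(), dtype="S1") for s in seqs]
    valid = [np.isin(a, [b"A", b"C", b"G", b"T"]) for a in arrs]
    vals = []
    sites = []
    for i, j in itertools.combinations(range(len(seqs)), 2):
        mask = valid[i] & valid[j]
        n_comp = int(mask.sum())
        if n_comp == 0:
            continue
        n_diff = int((arrs[i][mask] != arrs[j][mask]).sum())
        vals.append(n_diff / n_comp)
        sites.append(n_comp)
    if not vals:
        raise ValueError(f"{aln.gene}: no comparable sites in any pair")
    return DiversityResult(gene=aln.gene, pi=float(np.mean(vals)),
                           sites_used=float(np.mean(sites)), pairs_used=len(vals))


# --------------------------------------------------------------------- NG86

def nei_gojobori_pair(seq_a: str, seq_b: str, gene: str = "pair") -> KaKsResult:
    """NG86 Ka, Ks and their ratio for one pair of in-frame sequences.

    Codons containing '-' or 'N' in either sequence are dropped (pairwise
    deletion) and reported via ``codons_skipped``; an internal stop codon
    in either sequence is an error.
    """
    seq_a, seq_b = seq_a.upper(), seq_b.upper()
    if len(seq_a) != len(seq_b):
        raise ValueError("sequences differ in length")
    if len(seq_a) % 3:
        raise ValueError("sequence length not divisible by 3")
    n_codons = len(seq_a) // 3
    s_a = s_b = 0.0
    sd = nd = 0.0
    compared = skipped = 0
    for idx in range(n_codons):
        ca = seq_a[3 * idx: 3 * idx + 3]
        cb = seq_b[3 * idx: 3 * idx + 3]
        if set(ca + cb) - set("ACGT"):
            skipped += 1
            continue
        for name, codon in (("first", ca), ("second", cb)):
            if codon in STOP_CODONS and idx < n_codons - 1:
                raise ValueError(f"internal stop codon {codon} at codon {idx} "
                                 f"of the {name} sequence")
        if ca in STOP_CODONS or cb in STOP_CODONS:
            # terminal stop: carries no Ka/Ks information
            skipped += 1
            continue
        d_s, d_n, ok = _pair_diff(ca, cb)
        if not ok:
            skipped += 1
            continue
        s_a += _SYN_SITES[ca]
        s_b += _SYN_SITES[cb]
        sd += d_s
        nd += d_n
        compared += 1
    if compared == 0:
        return KaKsResult(gene=gene, s_sites=0.0, n_sites=0.0, ka=None, ks=None,
                          ratio=None, selection_class="undefined",
                          codons_compared=0, codons_skipped=skipped)
    s_bar = (s_a + s_b) / 2.0
    n_bar = 3.0 * compared - s_bar
    ps = sd / s_bar if s_bar > 0 else None
    pn = nd / n_bar if n_bar > 0 else None
    ks = jukes_cantor(ps) if ps is not None else None
    ka = jukes_cantor(pn) if pn is not None else None
    ratio = None
    if ka is not None and ks is not None and ks > 0:
        ratio = ka / ks
    return KaKsResult(gene=gene, s_sites=s_bar, n_sites=n_bar, ka=ka, ks=ks,
                      ratio=ratio, selection_class=_classify(ratio),
                      codons_compared=compared, codons_skipped=skipped)


def gene_kaks_summary(aln: CodonAlignment, min_length: int = 300,
                      neutral_tol: float = 1e-6) -> KaKsResult:
    """Gene-level Ka/Ks: means over all defined pairwise NG86 values.

    Pseudogenes and alignments shorter than ``min_length`` bp are excluded
    (``excluded_reason`` set, values undefined).  The gene ratio is
    ``mean(Ka) / mean(Ks)`` over pairs with defined distances; it is
    undefined when no pair is defined or mean Ks is 0.
    """
    if aln.pseudogene:
        return KaKsResult(gene=aln.gene, s_sites=0.0, n_sites=0.0, ka=None,
                          ks=None, ratio=None, selection_class="undefined",
                          excluded_reason="pseudogene")
    if aln.length < min_length:
        return KaKsResult(gene=aln.gene, s_sites=0.0, n_sites=0.0, ka=None,
                          ks=None, ratio=None, selection_class="undefined",
                          excluded_reason=f"length<{min_length}")
    if len(aln.records) < 2:
        raise ValueError(f"{aln.gene}: need >= 2 sequences")
    pair_results = [
        nei_gojobori_pair(a, b, gene=aln.gene)
        for (_, a), (_, b) in itertools.combinations(aln.records, 2)
    ]
    defined = [r for r in pair_results if r.ka is not None and r.ks is not None]
    skipped = sum(r.codons_skipped for r in pair_results)
    if not defined:
        return KaKsResult(gene=aln.gene, s_sites=0.0, n_sites=0.0, ka=None,
                          ks=None, ratio=None, selection_class="undefined",
                          codons_skipped=skipped)
    ka = float(np.mean([r.ka for r in defined]))
    ks = float(np.mean([r.ks for r in defined]))
    ratio = ka / ks if ks > 0 else None
    return KaKsResult(
        gene=aln.gene,
        s_sites=float(np.mean([r.s_sites for r in defined])),
        n_sites=float(np.mean([r.n_sites for r in defined])),
        ka=ka, ks=ks, ratio=ratio,
        selection_class=_classify(ratio, neutral_tol),
        codons_compared=int(np.mean([r.codons_compared for r in defined])),
        codons_skipped=skipped,
    )
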