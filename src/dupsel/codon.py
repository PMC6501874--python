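"""Genetic-code arithmetic: codon classification, pathway counting, site counting.

All dN/dS machinery rests on three primitives: classifying a single-base
codon change as synonymous or nonsynonymous, averaging synonymous and
nonsynonymous step counts over the minimal mutational pathways connecting
two codons, and Nei-Gojobori-style fractional site counting.  Counts are
fractional because multi-step pathways are averaged and because a codon
position can be partially degenerate.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping, Sequence

from Bio import SeqIO
from Bio.Data import CodonTable
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

NUCLEOTIDES = "ACGT"
STOP_SYMBOL = "*"
GAP_CHARS = set("-.")


class CodonValidationError(ValueError):
    """Raised when a sequence or alignment violates codon-frame invariants."""


@dataclass(frozen=True)
class GeneticCode:
    """A codon translation table over {A,C,G,T}^3.

    ``table`` maps all 64 codons to one-letter amino-acid symbols, with
    stop codons mapped to ``*``.  The standard code (NCBI table 1) is the
    default throughout the package; alternative tables can be injected.
    """

    table: Mapping[str, str]
    stop_codons: frozenset[str]

    @classmethod
    def standard(cls) -> "GeneticCode":
        ncbi = CodonTable.unambiguous_dna_by_id[1]
        table = dict(ncbi.forward_table)
        for stop in ncbi.stop_codons:
            table[stop] = STOP_SYMBOL
        return cls(table=table, stop_codons=frozenset(ncbi.stop_codons))

    def __post_init__(self) -> None:
        codons = {a + b + c for a in NUCLEOTIDES for b in NUCLEOTIDES for c in NUCLEOTIDES}
        if set(self.table) != codons:
            raise ValueError("genetic code table must cover all 64 codons exactly")
        for stop in self.stop_codons:
            if self.table[stop] != STOP_SYMBOL:
                raise ValueError(f"stop codon {stop} must translate to {STOP_SYMBOL!r}")

    def translate(self, codon: str) -> str:
        return self.table[codon]

    def is_stop(self, codon: str) -> bool:
        return codon in self.stop_codons

    @property
    def sense_codons(self) -> tuple[str, ...]:
        return tuple(sorted(c for c in self.table if c not in self.stop_codons))


_STANDARD = GeneticCode.standard()


def standard_code() -> GeneticCode:
    """The standard (NCBI table 1) genetic code."""
    return _STANDARD


def is_unambiguous_codon(codon: str) -> bool:
    return len(codon) == 3 and all(b in NUCLEOTIDES for b in codon)


@dataclass(frozen=True)
class PairCounts:
    """Fractional synonymous/nonsynonymous change counts between two codons.

    ``blocked`` flags pairs for which every minimal pathway crosses a stop
    codon; counts then come from the all-pathways fallback with stop steps
    scored as nonsynonymous, keeping syn + nsyn equal to the number of
    differing positions.
    """

    syn: float
    nsyn: float
    blocked: bool = False

    def __add__(self, other: "PairCounts") -> "PairCounts":
        return PairCounts(self.syn + other.syn, self.nsyn + other.nsyn,
                          self.blocked or other.blocked)


@dataclass(frozen=True)
class SiteCounts:
    """Fractional synonymous/nonsynonymous site counts (NG-style denominators)."""

    syn_sites: float
    nsyn_sites: float

    def __add__(self, other: "SiteCounts") -> "SiteCounts":
        return SiteCounts(self.syn_sites + other.syn_sites,
                          self.nsyn_sites + other.nsyn_sites)


def classify_single_change(c1: str, c2: str, code: GeneticCode | None = None) -> str:
    """Classify a single-base codon change as synonymous, nonsynonymous or nonsense.

    The codons must differ at exactly one position.  A change into a stop
    codon is ``"nonsense"``; otherwise the change is ``"synonymous"`` iff
    the translations agree.
    """
    code = code or _STANDARD
    if not (is_unambiguous_codon(c1) and is_unambiguous_codon(c2)):
        raise ValueError(f"not unambiguous codons: {c1!r}, {c2!r}")
    ndiff = sum(a != b for a, b in zip(c1, c2))
    if ndiff != 1:
        raise ValueError(f"codons {c1}/{c2} differ at {ndiff} positions, expected 1")
    if code.is_stop(c2):
        return "nonsense"
    if code.is_stop(c1):
        # leaving a stop: translations cannot agree with a sense codon
        return "nonsense"
    return "synonymous" if code.translate(c1) == code.translate(c2) else "nonsynonymous"


def _pathway_steps(c1: str, c2: str, order: Sequence[int]) -> Iterator[tuple[str, str]]:
    cur = list(c1)
    for pos in order:
        nxt = cur.copy()
        nxt[pos] = c2[pos]
        yield "".join(cur), "".join(nxt)
        cur = nxt


def pathway_counts(c1: str, c2: str, code: GeneticCode | None = None) -> PairCounts:
    """Average syn/nsyn step counts over minimal mutational pathways.

    All orderings of the differing positions are enumerated; pathways whose
    intermediate codons are stops are discarded and the per-pathway step
    counts averaged over the survivors.  Symmetric in its arguments.  If
    every pathway is stop-blocked, all pathways are averaged with stop
    steps counted as nonsynonymous and the result flagged.
    """
    code = code or _STANDARD
    for c in (c1, c2):
        if not is_unambiguous_codon(c) or code.is_stop(c):
            raise ValueError(f"pathway_counts requires sense codons, got {c!r}")
    diffs = [i for i in range(3) if c1[i] != c2[i]]
    if not diffs:
        return PairCounts(0.0, 0.0)

    valid: list[tuple[float, float]] = []
    fallback: list[tuple[float, float]] = []
    for order in itertools.permutations(diffs):
        syn = nsyn = 0.0
        ok = True
        for a, b in _pathway_steps(c1, c2, order):
            if code.is_stop(a) or code.is_stop(b):
                ok = False
                nsyn += 1.0
            elif code.translate(a) == code.translate(b):
                syn += 1.0
            else:
                nsyn += 1.0
        (valid if ok else fallback).append((syn, nsyn))
    if valid:
        syn = sum(s for s, _ in valid) / len(valid)
        nsyn = sum(n for _, n in valid) / len(valid)
        return PairCounts(syn, nsyn, blocked=False)
    allp = fallback
    syn = sum(s for s, _ in allp) / len(allp)
    nsyn = sum(n for _, n in allp) / len(allp)
    return PairCounts(syn, nsyn, blocked=True)


def ng_site_counts(codon: str, code: GeneticCode | None = None) -> SiteCounts:
    """Nei-Gojobori fractional site counts for one sense codon.

    At each position the synonymous-site fraction is the number of the
    three possible single-base changes that are synonymous, divided by 3;
    changes into stop codons count as nonsynonymous, so the two fractions
    sum to exactly 3 per codon.
    """
    code = code or _STANDARD
    if not is_unambiguous_codon(codon) or code.is_stop(codon):
        raise ValueError(f"ng_site_counts requires a sense codon, got {codon!r}")
    syn = 0.0
    for pos in range(3):
        for base in NUCLEOTIDES:
            if base == codon[pos]:
                continue
            alt = codon[:pos] + base + codon[pos + 1:]
            if not code.is_stop(alt) and code.translate(alt) == code.translate(codon):
                syn += 1.0
    syn /= 3.0
    return SiteCounts(syn, 3.0 - syn)


def iter_codons(seq: str) -> Iterator[str]:
    for i in range(0, len(seq), 3):
        yield seq[i:i + 3]


def alignment_site_counts(seq: str, code: GeneticCode | None = None) -> SiteCounts:
    """Sum of per-codon NG site counts over an in-frame sequence.

    Codons containing gaps or ambiguity codes are skipped (column-wise
    exclusion convention); internal stop codons are a validation error.
    """
    code = code or _STANDARD
    if len(seq) % 3:
        raise CodonValidationError(f"sequence length {len(seq)} not divisible by 3")
    total = SiteCounts(0.0, 0.0)
    for codon in iter_codons(seq.upper()):
        if not is_unambiguous_codon(codon):
            continue
        if code.is_stop(codon):
            raise CodonValidationError(f"internal stop codon {codon}")
        total = total + ng_site_counts(codon, code)
    return total


@dataclass
class CodonAlignment:
    """An in-frame codon alignment: equal-length sequences keyed by record id.

    Validation enforces frame (length divisible by 3), equal lengths, and
    the absence of internal stop codons.  Gap characters are only accepted
    when ``allow_gaps`` is set; gap-containing codon columns are excluded
    from all downstream counts.
    """

    ids: list[str]
    seqs: list[str]
    allow_gaps: bool = False
    code: GeneticCode = field(default_factory=standard_code)

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.seqs):
            raise CodonValidationError("ids and seqs length mismatch")
        if len(set(self.ids)) != len(self.ids):
            raise CodonValidationError("duplicate record ids")
        self.seqs = [s.upper() for s in self.seqs]
        lengths = {len(s) for s in self.seqs}
        if len(lengths) > 1:
            raise CodonValidationError(f"unequal sequence lengths: {sorted(lengths)}")
        if self.seqs and len(self.seqs[0]) % 3:
            raise CodonValidationError("alignment length not divisible by 3")
        for rid, seq in zip(self.ids, self.seqs):
            for j, codon in enumerate(iter_codons(seq)):
                has_gap = any(ch in GAP_CHARS for ch in codon)
                if has_gap and not self.allow_gaps:
                    raise CodonValidationError(
                        f"gap in record {rid!r} codon {j + 1} (allow_gaps not set)")
                if not has_gap and is_unambiguous_codon(codon) and self.code.is_stop(codon):
                    raise CodonValidationError(
                        f"stop codon {codon} in record {rid!r} codon {j + 1}")

    @property
    def n_seqs(self) -> int:
        return len(self.seqs)

    @property
    def n_codons(self) -> int:
        return len(self.seqs[0]) // 3 if self.seqs else 0

    def sequence(self, rid: str) -> str:
        return self.seqs[self.ids.index(rid)]

    def codon(self, i: int, j: int) -> str:
        """Codon j (0-based) of sequence i."""
        return self.seqs[i][3 * j:3 * j + 3]

    def column(self, j: int) -> list[str]:
        return [s[3 * j:3 * j + 3] for s in self.seqs]

    def clean_columns(self) -> list[int]:
        """Indices of columns in which every codon is unambiguous ACGT."""
        return [j for j in range(self.n_codons)
                if all(is_unambiguous_codon(c) for c in self.column(j))]

    def subset(self, ids: Sequence[str]) -> "CodonAlignment":
        return CodonAlignment(ids=list(ids),
                              seqs=[self.sequence(r) for r in ids],
                              allow_gaps=self.allow_gaps, code=self.code)

    @classmethod
    def from_fasta(cls, path: str | Path, allow_gaps: bool = False,
                   code: GeneticCode | None = None) -> "CodonAlignment":
        records = list(SeqIO.parse(str(path), "fasta"))
        if not records:
            raise CodonValidationError(f"no FASTA records in {path}")
        return cls(ids=[r.id for r in records], seqs=[str(r.seq) for r in records],
                   allow_gaps=allow_gaps, code=code or _STANDARD)

    def to_fasta(self, path: str | Path) -> None:
        records = [SeqRecord(Seq(s), id=i, description="") for i, s in zip(self.ids, self.seqs)]
        with open(path, "w") as fh:
            SeqIO.write(records, fh, "fasta")
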