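"""McDonald-Kreitman machinery with distance correction and suite bounds.

The MK test contrasts synonymous/nonsynonymous counts within species
(polymorphism, Ps/Pn) against counts between lineages (divergence, Ds/Dn)
in a 2x2 table.  Under neutrality the two ratios agree; an excess of
nonsynonymous divergence (Neutrality Index NI = (Pn/Ps)/(Dn/Ds) < 1)
indicates adaptive fixation.  Divergence counts are corrected for
multiple hits with the Jukes-Cantor map applied separately to synonymous
and nonsynonymous classes over Nei-Gojobori site denominators;
polymorphism counts, being recent, are left uncorrected.

When divergence is measured against a suite of reconstructed ancestral
sequences (one per constrained model), per-cell ranges and conservative
bounds are reported: NI as "<= max over members", chi-square as
">= min over members".
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.stats import chi2 as chi2_dist

from dupsel.codon import (CodonAlignment, GeneticCode, SiteCounts,
                          is_unambiguous_codon, iter_codons, ng_site_counts,
                          pathway_counts, standard_code)
from dupsel.ancestral import ReconstructionSuite

logger = logging.getLogger(__name__)


class SaturationError(ValueError):
    """Raised when a divergence proportion is beyond the Jukes-Cantor range."""


@dataclass
class PopulationSample:
    """Within-species haplotype sample for one gene."""

    gene_label: str
    haplotypes: CodonAlignment

    def __post_init__(self) -> None:
        if self.haplotypes.n_seqs < 2:
            raise ValueError("a population sample needs at least 2 haplotypes")

    @property
    def n(self) -> int:
        return self.haplotypes.n_seqs

    @property
    def n_codons(self) -> int:
        return self.haplotypes.n_codons

    def consensus(self, code: GeneticCode | None = None) -> str:
        """Majority-rule consensus; ties break to the smallest codon.

        Columns with any gap/ambiguous codon are emitted as ``---``.
        """
        out = []
        for j in range(self.n_codons):
            column = self.haplotypes.column(j)
            if not all(is_unambiguous_codon(c) for c in column):
                out.append("---")
                continue
            tally: dict[str, int] = {}
            for c in column:
                tally[c] = tally.get(c, 0) + 1
            best = max(sorted(tally), key=lambda c: tally[c])
            out.append(best)
        return "".join(out)


@dataclass
class MKCounts:
    """The cells of one MK comparison plus the site denominators used."""

    Ps: float
    Pn: float
    Ds_raw: float
    Dn_raw: float
    Ds: float
    Dn: float
    syn_sites: float
    nsyn_sites: float


@dataclass
class MKResult:
    """Neutrality Index and Pearson chi-square for one 2x2 MK table."""

    counts: Optional[MKCounts]
    NI: float
    chi2: float
    p: float
    ni_defined: bool = True
    chi2_defined: bool = True
    label: str = ""


@dataclass
class MKRangeResult:
    """Min-max cells and conservative bounds over a reconstruction suite."""

    Ps: float
    Pn: float
    Ds_range: tuple[float, float]
    Dn_range: tuple[float, float]
    NI_max: float
    chi2_min: float
    p_at_chi2_min: float
    members: list[MKResult] = field(default_factory=list)
    label: str = ""


# ---------------------------------------------------------------------------
# counting

def _usable_columns(*seq_sets: Sequence[str]) -> list[int]:
    n = len(seq_sets[0][0]) // 3
    cols = []
    for j in range(n):
        if all(is_unambiguous_codon(s[3 * j:3 * j + 3]) for seqs in seq_sets for s in seqs):
            cols.append(j)
    return cols


def _spanning_pairs(codons: list[str]) -> list[tuple[str, str]]:
    """Minimum-total-change spanning tree over distinct codons (Kruskal).

    Edges are weighted by Hamming distance with lexicographic tie-breaks,
    so the arrangement is deterministic.
    """
    uniq = sorted(set(codons))
    if len(uniq) < 2:
        return []
    edges = []
    for i, a in enumerate(uniq):
        for b in uniq[i + 1:]:
            d = sum(x != y for x, y in zip(a, b))
            edges.append((d, a, b))
    edges.sort()
    parent = {c: c for c in uniq}

    def find(c):
        while parent[c] != c:
            parent[c] = parent[parent[c]]
            c = parent[c]
        return c

    chosen = []
    for d, a, b in edges:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb
            chosen.append((a, b))
    return chosen


def count_polymorphisms(sample: PopulationSample,
                        code: GeneticCode | None = None) -> tuple[float, float]:
    """Fractional (Ps, Pn) from segregating codon columns.

    Distinct alleles in a column are connected by a minimum-total-change
    spanning arrangement; pathway counts are summed over its edges.
    Columns containing gaps or ambiguity codes are skipped.
    """
    code = code or standard_code()
    aln = sample.haplotypes
    Ps = Pn = 0.0
    for j in range(aln.n_codons):
        column = aln.column(j)
        if not all(is_unambiguous_codon(c) for c in column):
            if all(all(ch in "-." for ch in c) for c in column):
                logger.info("sample %s: all-gap codon column %d skipped",
                            sample.gene_label, j + 1)
            continue
        for a, b in _spanning_pairs(column):
            pc = pathway_counts(a, b, code)
            Ps += pc.syn
            Pn += pc.nsyn
    return Ps, Pn


def count_divergence(sample: PopulationSample, reference: str,
                     code: GeneticCode | None = None) -> tuple[float, float]:
    """Fractional (Ds_raw, Dn_raw): fixed differences sample vs reference.

    Only columns monomorphic within the sample contribute; polymorphic
    columns are polymorphism, not divergence (classic MKT convention).
    """
    code = code or standard_code()
    aln = sample.haplotypes
    if len(reference) != 3 * aln.n_codons:
        raise ValueError("reference length does not match the sample alignment")
    Ds = Dn = 0.0
    for j in range(aln.n_codons):
        column = aln.column(j)
        ref = reference[3 * j:3 * j + 3]
        if not all(is_unambiguous_codon(c) for c in column + [ref]):
            continue
        if len(set(column)) != 1:
            continue  # segregating: counted as polymorphism only
        fixed = column[0]
        if fixed != ref:
            pc = pathway_counts(fixed, ref, code)
            Ds += pc.syn
            Dn += pc.nsyn
    return Ds, Dn


def _pair_site_counts(seq_a: str, seq_b: str,
                      code: GeneticCode | None = None) -> SiteCounts:
    """NG site counts averaged between two sequences over shared clean columns."""
    code = code or standard_code()
    total_a = SiteCounts(0.0, 0.0)
    total_b = SiteCounts(0.0, 0.0)
    for ca, cb in zip(iter_codons(seq_a), iter_codons(seq_b)):
        if is_unambiguous_codon(ca) and is_unambiguous_codon(cb) \
                and not code.is_stop(ca) and not code.is_stop(cb):
            total_a = total_a + ng_site_counts(ca, code)
            total_b = total_b + ng_site_counts(cb, code)
    return SiteCounts(0.5 * (total_a.syn_sites + total_b.syn_sites),
                      0.5 * (total_a.nsyn_sites + total_b.nsyn_sites))


# ---------------------------------------------------------------------------
# distance correction and the test

def jc_correct(raw_count: float, sites: float) -> float:
    """Jukes-Cantor multiple-hit correction of a per-class divergence count.

    p = raw/sites; d = -(3/4) ln(1 - 4p/3); returns d * sites.  Raises
    :class:`SaturationError` at p >= 0.75.
    """
    if raw_count < 0 or sites < 0:
        raise ValueError("counts and sites must be nonnegative")
    if raw_count == 0:
        return 0.0
    if sites == 0:
        raise ValueError("cannot correct a positive count over zero sites")
    p = raw_count / sites
    if p >= 0.75:
        raise SaturationError(f"divergence proportion {p:.3f} >= 0.75: saturated")
    return -0.75 * math.log1p(-4.0 * p / 3.0) * sites


def mk_test(Ps: float, Pn: float, Ds: float, Dn: float,
            counts: Optional[MKCounts] = None, label: str = "") -> MKResult:
    """Neutrality Index and (uncorrected) Pearson chi-square of the MK table.

    NI = (Pn/Ps)/(Dn/Ds); flagged undefined when Ps, Ds or Dn is zero.
    The chi-square uses no continuity correction; its p-value is the
    chi-square(1) upper tail.
    """
    cells = np.array([[Ps, Pn], [Ds, Dn]], dtype=float)
    if (cells < 0).any():
        raise ValueError("MK cells must be nonnegative")
    if cells.sum() == 0:
        raise ValueError("all-zero MK table")
    ni_defined = Ps > 0 and Ds > 0 and Dn > 0
    NI = (Pn / Ps) / (Dn / Ds) if ni_defined else math.nan
    rows = cells.sum(axis=1)
    colsums = cells.sum(axis=0)
    chi2_defined = bool((rows > 0).all() and (colsums > 0).all())
    if chi2_defined:
        expected = np.outer(rows, colsums) / cells.sum()
        chi2 = float(((cells - expected) ** 2 / expected).sum())
        p = float(chi2_dist.sf(chi2, df=1))
    else:
        chi2, p = math.nan, math.nan
    return MKResult(counts=counts, NI=NI, chi2=chi2, p=p,
                    ni_defined=ni_defined, chi2_defined=chi2_defined, label=label)


def mk_counts(sample: PopulationSample, reference: str,
              code: GeneticCode | None = None) -> MKCounts:
    """Assemble the corrected MK cells for a sample-vs-reference comparison."""
    code = code or standard_code()
    Ps, Pn = count_polymorphisms(sample, code)
    Ds_raw, Dn_raw = count_divergence(sample, reference, code)
    sites = _pair_site_counts(sample.consensus(code), reference, code)
    Ds = jc_correct(Ds_raw, sites.syn_sites)
    Dn = jc_correct(Dn_raw, sites.nsyn_sites)
    return MKCounts(Ps=Ps, Pn=Pn, Ds_raw=Ds_raw, Dn_raw=Dn_raw, Ds=Ds, Dn=Dn,
                    syn_sites=sites.syn_sites, nsyn_sites=sites.nsyn_sites)


def mk_vs_reference(sample: PopulationSample, reference: str,
                    code: GeneticCode | None = None, label: str = "") -> MKResult:
    """Full MK test of a population sample against one reference sequence."""
    c = mk_counts(sample, reference, code)
    return mk_test(c.Ps, c.Pn, c.Ds, c.Dn, counts=c, label=label)


def mk_vs_reconstruction_suite(sample: PopulationSample,
                               suite: ReconstructionSuite,
                               code: GeneticCode | None = None,
                               label: str = "") -> MKRangeResult:
    """Conservative MK bounds over a suite of reconstructed ancestors.

    Each suite member serves as the divergence reference; the report
    carries per-cell min-max ranges, NI as "<= max member NI" and
    chi-square as ">= min member chi-square" with the p-value at that
    minimum.  Members whose comparison fails (e.g. saturation) are skipped
    with a notice; at least one member must survive.
    """
    code = code or standard_code()
    members: list[MKResult] = []
    for rec in suite.members:
        try:
            members.append(mk_vs_reference(sample, rec.map_codons, code,
                                           label=rec.model_label))
        except (SaturationError, ValueError) as exc:
            logger.warning("suite member %s skipped: %s", rec.model_label, exc)
    if not members:
        raise ValueError("no suite member produced a usable MK comparison")
    ds = [m.counts.Ds for m in members]
    dn = [m.counts.Dn for m in members]
    defined = [m for m in members if m.ni_defined]
    NI_max = max(m.NI for m in defined) if defined else math.nan
    with_chi = [m for m in members if m.chi2_defined]
    if with_chi:
        argmin = min(with_chi, key=lambda m: m.chi2)
        chi2_min, p_min = argmin.chi2, argmin.p
    else:
        chi2_min, p_min = math.nan, math.nan
    first = members[0].counts
    return MKRangeResult(Ps=first.Ps, Pn=first.Pn,
                         Ds_range=(min(ds), max(ds)), Dn_range=(min(dn), max(dn)),
                         NI_max=NI_max, chi2_min=chi2_min, p_at_chi2_min=p_min,
                         members=members, label=label or sample.gene_label)


def pairwise_mk(sample_a: PopulationSample, sample_b: PopulationSample,
                code: GeneticCode | None = None, label: str = "") -> MKResult:
    """Pooled MK comparison of two within-species gene samples.

    Polymorphism cells pool the two genes' within-sample counts;
    divergence is counted between the genes at columns fixed within both
    samples, Jukes-Cantor corrected over averaged consensus site counts.
    """
    code = code or standard_code()
    if sample_a.n_codons != sample_b.n_codons:
        raise ValueError("samples must share alignment length")
    Ps_a, Pn_a = count_polymorphisms(sample_a, code)
    Ps_b, Pn_b = count_polymorphisms(sample_b, code)
    Ps, Pn = Ps_a + Ps_b, Pn_a + Pn_b

    aln_a, aln_b = sample_a.haplotypes, sample_b.haplotypes
    Ds_raw = Dn_raw = 0.0
    for j in range(sample_a.n_codons):
        col_a = aln_a.column(j)
        col_b = aln_b.column(j)
        if not all(is_unambiguous_codon(c) for c in col_a + col_b):
            continue
        if len(set(col_a)) != 1 or len(set(col_b)) != 1:
            continue
        if col_a[0] != col_b[0]:
            pc = pathway_counts(col_a[0], col_b[0], code)
            Ds_raw += pc.syn
            Dn_raw += pc.nsyn
    sites = _pair_site_counts(sample_a.consensus(code), sample_b.consensus(code), code)
    Ds = jc_correct(Ds_raw, sites.syn_sites)
    Dn = jc_correct(Dn_raw, sites.nsyn_sites)
    counts = MKCounts(Ps=Ps, Pn=Pn, Ds_raw=Ds_raw, Dn_raw=Dn_raw, Ds=Ds, Dn=Dn,
                      syn_sites=sites.syn_sites, nsyn_sites=sites.nsyn_sites)
    return mk_test(Ps, Pn, Ds, Dn, counts=counts,
                   label=label or f"{sample_a.gene_label} vs {sample_b.gene_label}")
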