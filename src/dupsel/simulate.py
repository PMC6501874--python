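"""Synthetic codon alignments and population samples with known truth.

Two generators cover the two statistical structures the pipeline assumes:

- ``simulate_alignment`` evolves codon sequences down a labelled tree
  under the same site-class/branch-class omega regime the branch-site
  models fit, returning the tip alignment together with the true site
  classes (for posterior-calibration oracles).
- ``simulate_population_sample`` overlays Poisson-distributed single-base
  polymorphisms on a base haplotype at controlled synonymous and
  nonsynonymous intensities — the count structure the MK test consumes.
  No coalescent genealogy is modelled; allele frequencies are uniform.

All randomness flows from one seed through ``numpy.random.default_rng``,
so identical scenarios reproduce byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from dupsel.codon import CodonAlignment, GeneticCode, standard_code
from dupsel.codonmodel import CodonModelParams, _EigenQ, _raw_rate_matrix, mean_rate
from dupsel.retention import FunctionAnnotation
from dupsel.trees import PhyloTree

CLASS_LABELS = ("0", "1", "2a", "2b")


@dataclass
class SimulationScenario:
    """A tree with foreground marks plus true codon-model parameters.

    ``params.p0/p1/omega2`` may be omitted for single-class (M0-style)
    simulation.  Branch lengths are expected substitutions per codon under
    the same background-mixture scaling the likelihood engine uses, so
    fitted values are directly comparable with the truth.
    """

    tree: PhyloTree
    params: CodonModelParams
    n_codons: int
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_codons < 1:
            raise ValueError("n_codons must be positive")


@dataclass
class PopulationScenario:
    """Poisson-overlay polymorphism scenario for one gene sample."""

    base_sequence: str
    n_haplotypes: int
    theta_syn: float
    theta_nsyn: float
    seed: int = 0
    gene_label: str = "sim"

    def __post_init__(self) -> None:
        if self.n_haplotypes < 2:
            raise ValueError("need at least 2 haplotypes")
        if self.theta_syn < 0 or self.theta_nsyn < 0:
            raise ValueError("intensities must be nonnegative")
        if len(self.base_sequence) % 3:
            raise ValueError("base sequence must be in frame")


def _class_draw(params: CodonModelParams, n: int, rng: np.random.Generator) -> np.ndarray:
    if params.p0 is None:
        return np.zeros(n, dtype=int)
    return rng.choice(4, size=n, p=params.class_proportions())


def simulate_alignment(scenario: SimulationScenario,
                       code: GeneticCode | None = None
                       ) -> tuple[CodonAlignment, np.ndarray]:
    """Evolve a codon alignment along the scenario tree.

    Returns the tip alignment and the per-site true class index (always 0
    for single-class scenarios).  Root states are drawn from the
    stationary distribution (sense codons only by construction).
    """
    code = code or standard_code()
    params = scenario.params
    rng = np.random.default_rng(scenario.seed)
    tree = scenario.tree.unrooted_canonical()
    n = scenario.n_codons
    classes = _class_draw(params, n, rng)

    pi = np.asarray(params.pi, dtype=float)
    w0 = params.omega0
    w2 = params.omega2 if params.omega2 is not None else 1.0
    if params.p0 is None:
        omegas_bg = {0: w0}
        omegas_fg = {0: w0}
        scale = mean_rate(params.kappa, pi, w0, code)
    else:
        omegas_bg = {0: w0, 1: 1.0, 2: w0, 3: 1.0}
        omegas_fg = {0: w0, 1: 1.0, 2: w2, 3: w2}
        props = params.class_proportions()
        scale = ((props[0] + props[2]) * mean_rate(params.kappa, pi, w0, code)
                 + (props[1] + props[3]) * mean_rate(params.kappa, pi, 1.0, code))
    scale = max(scale, 1e-12)

    eigs = {w: _EigenQ(_raw_rate_matrix(params.kappa, pi, w, code) / scale, pi)
            for w in set(omegas_bg.values()) | set(omegas_fg.values())}

    root_states = rng.choice(61, size=n, p=pi / pi.sum())
    states = {id(tree.root): root_states}
    for node in tree.preorder():
        if node.parent is None:
            continue
        parent_states = states[id(node.parent)]
        child = np.empty(n, dtype=int)
        omega_of = omegas_fg if node.foreground else omegas_bg
        for cls in np.unique(classes):
            sel = classes == cls
            P = eigs[omega_of[int(cls)]].transition_matrices(np.array([node.length]))[0]
            P = P / P.sum(axis=1, keepdims=True)
            cum = np.cumsum(P, axis=1)
            u = rng.random(sel.sum())
            child[sel] = (cum[parent_states[sel]] < u[:, None]).sum(axis=1)
        states[id(node)] = np.minimum(child, 60)
    codons = code.sense_codons
    ids, seqs = [], []
    for tip in tree.tips():
        ids.append(tip.label)
        seqs.append("".join(codons[s] for s in states[id(tip)]))
    return CodonAlignment(ids=ids, seqs=seqs, code=code), classes


def simulate_population_sample(scenario: PopulationScenario,
                               code: GeneticCode | None = None):
    """Overlay Poisson polymorphisms on a base haplotype.

    Synonymous and nonsynonymous single-base changes arrive as Poisson
    counts with means ``theta_syn * n_codons`` and ``theta_nsyn *
    n_codons``; each derived allele is assigned to a uniform nonempty
    proper subset of haplotypes so every event stays segregating.  Changes
    creating stop codons are rejected and resampled.
    """
    from dupsel.mk import PopulationSample

    code = code or standard_code()
    rng = np.random.default_rng(scenario.seed)
    base = scenario.base_sequence.upper()
    n_codons = len(base) // 3
    haps = [list(base) for _ in range(scenario.n_haplotypes)]

    def sample_event(want_syn: bool, tries: int = 2000):
        from dupsel.codon import classify_single_change
        for _ in range(tries):
            j = int(rng.integers(n_codons))
            pos = int(rng.integers(3))
            codon = base[3 * j:3 * j + 3]
            if code.is_stop(codon):
                continue
            alt_base = "ACGT"[int(rng.integers(4))]
            if alt_base == codon[pos]:
                continue
            alt = codon[:pos] + alt_base + codon[pos + 1:]
            if code.is_stop(alt):
                continue
            kind = classify_single_change(codon, alt, code)
            if (kind == "synonymous") == want_syn:
                return j, pos, alt_base
        return None

    n_syn = rng.poisson(scenario.theta_syn * n_codons)
    n_nsyn = rng.poisson(scenario.theta_nsyn * n_codons)
    events = [True] * n_syn + [False] * n_nsyn
    for want_syn in events:
        ev = sample_event(want_syn)
        if ev is None:
            continue
        j, pos, alt_base = ev
        freq = int(rng.integers(1, scenario.n_haplotypes))
        carriers = rng.choice(scenario.n_haplotypes, size=freq, replace=False)
        for h in carriers:
            idx = 3 * j + pos
            old = haps[h][idx]
            haps[h][idx] = alt_base
            codon = "".join(haps[h][3 * j:3 * j + 3])
            if code.is_stop(codon):
                haps[h][idx] = old  # combination would create a stop: skip carrier
    aln = CodonAlignment(ids=[f"hap{i + 1}" for i in range(scenario.n_haplotypes)],
                         seqs=["".join(h) for h in haps], code=code)
    return PopulationSample(gene_label=scenario.gene_label, haplotypes=aln)


def simulate_divergent_reference(base_sequence: str, theta_syn: float,
                                 theta_nsyn: float, seed: int = 0,
                                 code: GeneticCode | None = None) -> str:
    """A fixed diverged partner for MK divergence counting.

    Applies Poisson(theta * n_codons) synonymous and nonsynonymous
    single-base substitutions to the base sequence itself (every
    haplotype of the diverged lineage carries them), rejecting changes
    that would create stop codons.
    """
    code = code or standard_code()
    rng = np.random.default_rng(seed)
    seq = list(base_sequence.upper())
    n_codons = len(seq) // 3
    from dupsel.codon import classify_single_change

    def apply_events(n_events: int, want_syn: bool) -> None:
        placed = 0
        tries = 0
        while placed < n_events and tries < 200 * max(n_events, 1):
            tries += 1
            j = int(rng.integers(n_codons))
            pos = int(rng.integers(3))
            codon = "".join(seq[3 * j:3 * j + 3])
            if code.is_stop(codon):
                continue
            alt_base = "ACGT"[int(rng.integers(4))]
            if alt_base == codon[pos]:
                continue
            alt = codon[:pos] + alt_base + codon[pos + 1:]
            if code.is_stop(alt):
                continue
            if (classify_single_change(codon, alt, code) == "synonymous") == want_syn:
                seq[3 * j + pos] = alt_base
                placed += 1

    apply_events(int(rng.poisson(theta_syn * n_codons)), True)
    apply_events(int(rng.poisson(theta_nsyn * n_codons)), False)
    return "".join(seq)


class ScenarioPreset(NamedTuple):
    """A duplication scenario plus the function-annotation fixture for it."""

    name: str
    scenario: SimulationScenario
    daughter_lineages: tuple[tuple[str, ...], tuple[str, ...]]
    annotations: dict[str, FunctionAnnotation]
    expected_mode: str


LINEAGE_A = ("dupA", "G1a", "G1b")
LINEAGE_B = ("dupB", "G2a", "G2b")

_PRESET_NEWICK = ("((G1a:0.25,G1b:0.25)dupA:0.3,(G2a:0.25,G2b:0.25)dupB:0.3,"
                  "(Out1:0.12,Out2:0.12)outg:0.16);")


def _equal_pi() -> np.ndarray:
    return np.full(61, 1.0 / 61)


def scenario_presets(n_codons: int = 300, seed: int = 20) -> dict[str, ScenarioPreset]:
    """Named duplication scenarios on a 6-tip tree: neutral, NF, EAC, CN.

    The tree holds two daughter-gene clades of the duplication (stems
    ``dupA``/``dupB`` with two sampled descendants each) plus an outgroup
    pair.  Episodic positive selection after a duplication acts along the
    whole daughter lineage, so selection scenarios mark the stem and its
    descendant branches jointly, with omega2 = 4 on about 10% of sites
    (p0 = 0.72, p1 = 0.18); the neutral scenario fixes omega2 = 1
    everywhere.  Function-annotation fixtures distinguish EAC from CN,
    which share the selection pattern.
    """
    def make(name, marks, omega2, annots, expected, offset):
        tree = PhyloTree.from_newick(_PRESET_NEWICK)
        if marks:
            tree.mark_foreground(*marks)
        params = CodonModelParams(kappa=2.0, pi=_equal_pi(), omega0=0.2,
                                  omega2=omega2, p0=0.72, p1=0.18)
        scen = SimulationScenario(tree=tree, params=params, n_codons=n_codons,
                                  seed=seed + offset)
        annotations = {cid: FunctionAnnotation(cid, state) for cid, state in annots}
        return ScenarioPreset(name=name, scenario=scen,
                              daughter_lineages=(LINEAGE_A, LINEAGE_B),
                              annotations=annotations, expected_mode=expected)

    return {
        "neutral": make("neutral", (), 1.0,
                        [("dupA", "ancestral"), ("dupB", "ancestral")],
                        "SF-or-ambiguous", 0),
        "NF": make("NF", LINEAGE_B, 4.0,
                   [("dupA", "ancestral"), ("dupB", "novel")], "NF", 1),
        "EAC": make("EAC", LINEAGE_A + LINEAGE_B, 4.0,
                    [("dupA", "ancestral"), ("dupB", "novel")], "EAC", 2),
        "CN": make("CN", LINEAGE_A + LINEAGE_B, 4.0,
                   [("dupA", "novel"), ("dupB", "novel-variant")], "CN", 3),
    }
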