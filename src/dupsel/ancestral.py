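"""Marginal ancestral codon-sequence reconstruction under fitted models.

For a fitted codon model, the marginal posterior of the ancestral state at
an internal node is obtained by rerooting the tree at that node (valid
under reversibility) and combining the partial likelihoods of all incident
subtrees with the stationary prior.  For branch-site mixtures the
posterior is marginalized over site classes with their estimated
proportions — a naive empirical-Bayes treatment at the maximum-likelihood
estimates.

Reconstruction "suites" fit several constrained models (e.g. M0, the
branch-site alternative with omega2 > 1, and the branch-site null with
omega2 = 1 at a key branch) and reconstruct the same node under each,
giving a family of plausible ancestral sequences whose downstream
McDonald-Kreitman statistics are reported as conservative bounds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy.special import logsumexp

from dupsel.codon import CodonAlignment, GeneticCode, standard_code
from dupsel.codonmodel import (CodonModelSpec, LikelihoodEngine, ModelFit, fit)
from dupsel.trees import PhyloTree

_TIE_TOL = 1e-12


@dataclass
class ReconstructedSequence:
    """MAP ancestral codon sequence at one node under one model.

    ``map_codons`` has one codon per alignment column, with ``---`` at
    columns dropped from the likelihood (gaps/ambiguity).
    ``site_posteriors`` holds the posterior probability of the MAP codon
    (NaN at dropped columns); ``posterior_matrix`` the full per-site
    posterior over the 61 sense codons.
    """

    node_id: str
    model_label: str
    map_codons: str
    site_posteriors: np.ndarray
    posterior_matrix: np.ndarray = field(repr=False)
    tied_sites: list[int] = field(default_factory=list)
    converged: bool = True

    @property
    def n_codons(self) -> int:
        return len(self.map_codons) // 3


@dataclass
class ReconstructionSuite:
    """Reconstructions of one node under each model of a constrained suite."""

    node_id: str
    members: list[ReconstructedSequence]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("a reconstruction suite needs at least one member")
        lengths = {len(m.map_codons) for m in self.members}
        nodes = {m.node_id for m in self.members}
        if len(lengths) > 1 or nodes != {self.node_id}:
            raise ValueError("suite members must share node and length")

    def labels(self) -> list[str]:
        return [m.model_label for m in self.members]


def marginal_reconstruction(fit_result: ModelFit, aln: CodonAlignment,
                            tree: PhyloTree, node_id: str | int,
                            code: GeneticCode | None = None) -> ReconstructedSequence:
    """Marginal MAP reconstruction of the codon sequence at an internal node.

    The posterior over the 61 sense codons is computed per site from the
    fitted model's parameters and branch lengths; the MAP codon is
    reported with its posterior, breaking exact ties toward the
    lexicographically smallest codon (tied sites are recorded).
    """
    code = code or standard_code()
    target = tree.find(node_id)
    if target.is_tip:
        raise ValueError(f"node {node_id!r} is a tip; reconstruction needs an internal node")
    if not fit_result.converged:
        raise ValueError("refusing to reconstruct from an unconverged fit")

    canon = tree.unrooted_canonical()
    canon_target = _match_node(tree, target, canon)
    rooted = canon.rerooted_at(canon_target.label) if canon_target is not canon.root else canon
    engine = LikelihoodEngine(aln, rooted, fit_result.spec, code=code,
                              pi=fit_result.params.pi, canonicalize=False)
    tvec = engine._branch_lengths_vector(fit_result.branch_lengths)
    logjoint, weights = engine.class_root_log_partials(fit_result.params, t_vector=tvec)
    keep = weights > 0
    logw = np.log(weights[keep])
    # P(state | data) marginalized over site classes
    mixed = logsumexp(logjoint[keep] + logw[:, None, None], axis=0)  # (61, npat)
    logpost = mixed - logsumexp(mixed, axis=0, keepdims=True)
    post = np.exp(logpost)

    codons = code.sense_codons
    n = aln.n_codons
    posterior_matrix = np.full((n, 61), np.nan)
    map_codons = ["---"] * n
    site_post = np.full(n, np.nan)
    tied: list[int] = []
    for col, pat in zip(engine.kept_columns, engine.pattern_of_column):
        vec = post[:, pat]
        posterior_matrix[col] = vec
        best = int(np.argmax(vec))
        if np.sum(vec >= vec[best] - _TIE_TOL) > 1:
            tied.append(col)
        map_codons[col] = codons[best]
        site_post[col] = float(vec[best])
    return ReconstructedSequence(node_id=target.label,
                                 model_label=_model_label(fit_result),
                                 map_codons="".join(map_codons),
                                 site_posteriors=site_post,
                                 posterior_matrix=posterior_matrix,
                                 tied_sites=tied,
                                 converged=fit_result.converged)


def _tips_below(node) -> frozenset:
    out = set()
    stack = [node]
    while stack:
        n = stack.pop()
        if n.is_tip:
            out.add(n.label)
        stack.extend(n.children)
    return frozenset(out)


def _match_node(tree: PhyloTree, target, canon: PhyloTree):
    """Locate ``target`` of ``tree`` inside its canonicalized copy.

    Matching is by the tip set below the node, which survives the collapse
    of a basal bifurcation; a node absorbed into the canonical root (the
    two are the same point of the unrooted tree) maps to the root.
    """
    want = _tips_below(target)
    for node in canon.preorder():
        if node is not canon.root and _tips_below(node) == want:
            return node
    return canon.root


def _model_label(fit_result: ModelFit) -> str:
    base = fit_result.spec.label()
    if fit_result.spec.is_branch_site and fit_result.tree is not None:
        marks = ",".join(n.label for n in fit_result.tree.foreground)
        if marks:
            base += f" @{marks}"
    return base


def reconstruction_suite(aln: CodonAlignment, tree: PhyloTree, node_id: str | int,
                         specs: Sequence[CodonModelSpec], seed: int = 0, *,
                         foregrounds: Optional[Sequence[Sequence[str | int]]] = None,
                         n_starts: int = 2,
                         code: GeneticCode | None = None) -> ReconstructionSuite:
    """Fit each model spec and reconstruct the same node under each.

    ``foregrounds`` optionally gives, per spec, the branches to mark as
    foreground (branch-site specs require one).  Unconverged member fits
    are retained in the suite with their ``converged`` flag cleared.
    """
    if not specs:
        raise ValueError("at least one model spec is required")
    members = []
    for k, spec in enumerate(specs):
        work = tree
        if foregrounds is not None and foregrounds[k]:
            work = tree.with_foreground(*foregrounds[k])
        fitted = fit(aln, work, spec, seed=seed + 17 * k, n_starts=n_starts, code=code)
        rec = _reconstruct_lenient(fitted, aln, work, node_id, code)
        members.append(rec)
    target_label = tree.find(node_id).label
    return ReconstructionSuite(node_id=target_label, members=members)


def _reconstruct_lenient(fitted: ModelFit, aln: CodonAlignment, tree: PhyloTree,
                         node_id: str | int, code: GeneticCode | None):
    converged = fitted.converged
    if not converged:
        fitted.converged = True  # reconstruct anyway, flag the member
    rec = marginal_reconstruction(fitted, aln, tree, node_id, code=code)
    rec.converged = converged
    fitted.converged = converged
    return rec


def write_suite_fasta(suite: ReconstructionSuite, path: str | Path) -> None:
    """Write suite members as FASTA with the model label in the description."""
    lines = []
    for i, m in enumerate(suite.members):
        lines.append(f">{suite.node_id}|{i} {m.model_label}")
        seq = m.map_codons
        for j in range(0, len(seq), 60):
            lines.append(seq[j:j + 60])
    Path(path).write_text("\n".join(lines) + "\n")


def write_posterior_table(rec: ReconstructedSequence, path: str | Path) -> None:
    """Per-site TSV: 1-based site, MAP codon, posterior of the MAP state."""
    lines = ["site\tmap_codon\tposterior"]
    for i in range(rec.n_codons):
        codon = rec.map_codons[3 * i:3 * i + 3]
        p = rec.site_posteriors[i]
        lines.append(f"{i + 1}\t{codon}\t" + ("NA" if np.isnan(p) else f"{p:.6f}"))
    Path(path).write_text("\n".join(lines) + "\n")
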