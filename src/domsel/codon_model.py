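"""Codon substitution model and pruning likelihood on a tagged tree.

The model is the classical reversible codon model: instantaneous rates are
nonzero only between codons differing at a single nucleotide position,
proportional to the target codon's stationary frequency, multiplied by
kappa for transitions and by the branch class's omega (dN/dS) for
nonsynonymous changes.  Each class matrix is scaled so that branch lengths
are expected substitutions per codon at stationarity.

Likelihoods are computed by Felsenstein pruning over compressed site
patterns, with per-node rescaling to avoid underflow.  The matrix
exponential uses an eigendecomposition of the frequency-symmetrised
generator (exact for reversible models), falling back to
scipy's scaling-and-squaring if the decomposition fails.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import expm as _expm

from .alignment import MISSING, CodonAlignment
from .codes import GeneticCode, STANDARD_CODE, is_transition
from .trees import TaggedTree

_EPS_SIMPLEX = 1e-10


def _pair_structure(code: GeneticCode):
    """Index arrays over ordered single-nucleotide-difference codon pairs.

    Returns (I, J, transition_mask, nonsyn_mask); cached per code object.
    """
    cached = getattr(code, "__pair_struct", None)
    if cached is not None:
        return cached
    I, J, ts, ns = [], [], [], []
    sense = code.sense_codons
    for i, ci in enumerate(sense):
        for j, cj in enumerate(sense):
            if i == j:
                continue
            diffs = [(a, b) for a, b in zip(ci, cj) if a != b]
            if len(diffs) != 1:
                continue
            I.append(i)
            J.append(j)
            ts.append(is_transition(*diffs[0]))
            ns.append(code.translate(ci) != code.translate(cj))
    out = (np.array(I), np.array(J), np.array(ts), np.array(ns))
    object.__setattr__(code, "__pair_struct", out)
    return out


@dataclass
class CodonModelParams:
    """Parameters of the branch-class codon model.

    ``omega_by_class`` maps branch class (WILD/DOMESTIC) to its dN/dS; a
    one-ratio model simply maps both classes to the same value.
    """

    kappa: float
    omega_by_class: dict
    codon_freqs: np.ndarray
    freq_model: str = "F3X4"
    code: GeneticCode = field(default=STANDARD_CODE, repr=False)

    def __post_init__(self):
        self.codon_freqs = np.asarray(self.codon_freqs, dtype=float)
        if self.kappa <= 0:
            raise ValueError(f"kappa must be positive, got {self.kappa}")
        for cls, w in self.omega_by_class.items():
            if w <= 0:
                raise ValueError(f"omega[{cls}] must be positive, got {w}")
        if self.codon_freqs.shape != (self.code.n_states,):
            raise ValueError("codon_freqs has wrong length")
        if (self.codon_freqs < 0).any() or abs(self.codon_freqs.sum() - 1.0) > _EPS_SIMPLEX:
            raise ValueError("codon_freqs is not a probability simplex")


def build_rate_matrix(params: CodonModelParams, branch_class: str) -> np.ndarray:
    """Scaled instantaneous rate matrix for one branch class.

    Rows sum to zero and the mean rate at stationarity is 1, so branch
    lengths are expected substitutions per codon.
    """
    if branch_class not in params.omega_by_class:
        raise ValueError(f"unknown branch class {branch_class!r}")
    omega = params.omega_by_class[branch_class]
    I, J, ts, ns = _pair_structure(params.code)
    pi = params.codon_freqs
    n = params.code.n_states
    rates = pi[J] * np.where(ts, params.kappa, 1.0) * np.where(ns, omega, 1.0)
    Q = np.zeros((n, n))
    Q[I, J] = rates
    np.fill_diagonal(Q, -Q.sum(axis=1))
    scale = -(pi * np.diag(Q)).sum()
    if scale <= 0:
        raise ValueError("degenerate rate matrix (zero total rate)")
    return Q / scale


def synonymous_rate_fraction(params: CodonModelParams, branch_class: str) -> float:
    """Fraction of the total substitution flux that is synonymous."""
    Q = build_rate_matrix(params, branch_class)
    I, J, _, ns = _pair_structure(params.code)
    pi = params.codon_freqs
    flux = pi[I] * Q[I, J]
    total = flux.sum()
    return float(flux[~ns].sum() / total)


class _Decomposition:
    """Spectral decomposition of a reversible generator for fast expm."""

    def __init__(self, Q: np.ndarray, pi: np.ndarray):
        self.Q = Q
        sqrt_pi = np.sqrt(pi)
        B = (sqrt_pi[:, None] * Q) / sqrt_pi[None, :]
        try:
            w, V = np.linalg.eigh((B + B.T) / 2.0)
            self.ok = True
            self.w = w
            self.left = V.T * sqrt_pi[None, :]          # V^T D
            self.right = V / sqrt_pi[:, None]           # D^-1 V
        except np.linalg.LinAlgError:
            self.ok = False

    def expm(self, t: float) -> np.ndarray:
        if not self.ok:
            return _expm(self.Q * t)
        P = (self.right * np.exp(self.w * t)[None, :]) @ self.left
        np.maximum(P, 0.0, out=P)
        return P


def transition_matrix(params: CodonModelParams, branch_class: str,
                      t: float) -> np.ndarray:
    """P(t) = exp(Q t) for one branch class."""
    Q = build_rate_matrix(params, branch_class)
    return _Decomposition(Q, params.codon_freqs).expm(t)


class PruningLikelihood:
    """Reusable pruning-likelihood engine for one gene.

    Site patterns are compressed once at construction; each call to
    :meth:`lnl` rebuilds the (cheap) class rate matrices and traverses
    the tree, so repeated evaluation during optimisation stays fast.
    """

    def __init__(self, aln: CodonAlignment, tree: TaggedTree):
        tree.check_taxa(aln.taxa)
        self.tree = tree
        self.code = aln.code
        n_states = self.code.n_states

        states = aln.state_matrix()
        patterns, weights = np.unique(states, axis=1, return_counts=True)
        self.pattern_weights = weights.astype(float)
        self.n_patterns = patterns.shape[1]

        taxon_row = {name: i for i, name in enumerate(aln.taxa)}
        self._leaf_partials = {}
        for leaf in tree.leaves:
            row = patterns[taxon_row[leaf.name]]
            part = np.zeros((n_states, self.n_patterns))
            obs = row != MISSING
            part[row[obs], np.nonzero(obs)[0]] = 1.0
            part[:, ~obs] = 1.0  # missing codon: sum over all states
            self._leaf_partials[leaf.branch_id] = part
        # decomposition cache: gradient steps that only move branch
        # lengths reuse the (kappa, omega) generator unchanged
        self._decomp_cache = {}

    def _decomposition(self, params: CodonModelParams, cls: str):
        key = (cls, params.kappa, params.omega_by_class[cls])
        hit = self._decomp_cache.get(key)
        if hit is None:
            if len(self._decomp_cache) > 64:
                self._decomp_cache.clear()
            hit = _Decomposition(build_rate_matrix(params, cls),
                                 params.codon_freqs)
            self._decomp_cache[key] = hit
        return hit

    def lnl(self, params: CodonModelParams) -> float:
        """Log-likelihood of the alignment on the current tree lengths."""
        decomp = {cls: self._decomposition(params, cls)
                  for cls in {b.branch_class for b in self.tree.branches}}
        log_scale = np.zeros(self.n_patterns)

        def partial(node):
            if node.is_leaf:
                return self._leaf_partials[node.branch_id]
            out = None
            for child in node.children:
                if not np.isfinite(child.length):
                    raise ValueError(
                        f"non-finite branch length on {child.branch_id}")
                P = decomp[child.branch_class].expm(child.length)
                down = P @ partial(child)
                out = down if out is None else out * down
            # rescale only when close to underflow
            if out.max() < 1e-200:
                mx = out.max(axis=0)
                mx[mx == 0.0] = 1.0
                nonlocal log_scale
                log_scale = log_scale + np.log(mx)
                out = out / mx
            return out

        root_part = partial(self.tree.root)
        site_l = params.codon_freqs @ root_part
        if (site_l <= 0).any():
            return -np.inf
        return float(self.pattern_weights @ (np.log(site_l) + log_scale))


def log_likelihood(aln: CodonAlignment, tree: TaggedTree,
                   params: CodonModelParams) -> float:
    """One-shot pruning log-likelihood (see :class:`PruningLikelihood`)."""
    return PruningLikelihood(aln, tree).lnl(params)
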