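"""Maximum-likelihood fitting of one-ratio and two-ratios codon models.

The one-ratio model (ORM) gives every branch the same dN/dS; the
two-ratios model (TRM) gives WILD and DOMESTIC branches separate ratios.
The models are nested with one extra parameter, so twice the
log-likelihood gain is referred to a chi-square with one degree of
freedom.  The TRM search starts at the ORM optimum (with both omegas set
to the shared estimate), which guarantees a non-negative statistic up to
optimizer tolerance.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.stats import chi2

from .alignment import CodonAlignment, codon_frequencies
from .codon_model import CodonModelParams, PruningLikelihood, synonymous_rate_fraction
from .trees import DOMESTIC, WILD, TaggedTree

EXTREME_NONE = "NONE"
EXTREME_NO_SYN = "NO_SYNONYMOUS"
EXTREME_NO_NONSYN = "NO_NONSYNONYMOUS"


@dataclass
class FitConfig:
    """Knobs of the per-gene model fit.

    omega and kappa are optimised in log space within the given bounds;
    branch lengths are optimised jointly with them unless
    ``optimize_branch_lengths`` is false, in which case the input tree's
    lengths are trusted (expected substitutions per codon).
    """

    freq_model: str = "F3X4"
    omega_bounds: tuple = (1e-4, 999.0)
    kappa_bounds: tuple = (1e-3, 100.0)
    branch_length_bounds: tuple = (1e-7, 20.0)
    optimize_branch_lengths: bool = True
    n_restarts: int = 0
    p_threshold: float = 0.05
    syn_divergence_floor: float = 1e-6
    lnl_tol: float = 1e-6
    max_iter: int = 500
    seed: int = 0


@dataclass
class GeneFitResult:
    gene_id: str
    lnL_ORM: float
    lnL_TRM: float
    omega_shared: float
    omega_W: float
    omega_D: float
    kappa_ORM: float
    kappa_TRM: float
    lrt_stat: float
    df: int
    p_value: float
    extreme_flag: str
    significant: bool
    converged: bool
    n_codons: int = 0

    TSV_COLUMNS = ("gene_id", "lnL_ORM", "lnL_TRM", "omega_shared",
                   "omega_W", "omega_D", "lrt_stat", "p_value",
                   "extreme_flag", "significant")

    def tsv_row(self) -> dict:
        return {c: getattr(self, c) for c in self.TSV_COLUMNS}


def lrt_pvalue(lnl_orm: float, lnl_trm: float) -> tuple:
    """Likelihood-ratio statistic and chi-square(1) upper-tail p-value."""
    if not (np.isfinite(lnl_orm) and np.isfinite(lnl_trm)):
        raise ValueError("non-finite log-likelihood in LRT")
    stat = max(0.0, 2.0 * (lnl_trm - lnl_orm))
    return stat, float(chi2.sf(stat, df=1))


class _Objective:
    """Negative log-likelihood over a packed log-parameter vector."""

    def __init__(self, engine: PruningLikelihood, tree: TaggedTree,
                 freqs: np.ndarray, freq_model: str, classes: list,
                 config: FitConfig):
        self.engine = engine
        self.tree = tree
        self.freqs = freqs
        self.freq_model = freq_model
        self.classes = classes  # branch classes sharing one omega slot each
        self.config = config
        self.branch_nodes = tree.branches if config.optimize_branch_lengths else []
        self.best = (np.inf, None)

    @property
    def n_params(self) -> int:
        return 1 + len(self.classes) + len(self.branch_nodes)

    def bounds(self):
        c = self.config
        logb = lambda lo_hi: (np.log(lo_hi[0]), np.log(lo_hi[1]))
        return ([logb(c.kappa_bounds)]
                + [logb(c.omega_bounds)] * len(self.classes)
                + [logb(c.branch_length_bounds)] * len(self.branch_nodes))

    def pack(self, kappa, omegas, lengths=None):
        x = [np.log(kappa)] + [np.log(w) for w in omegas]
        if self.branch_nodes:
            src = lengths if lengths is not None else [
                n.length for n in self.branch_nodes]
            lo, hi = self.config.branch_length_bounds
            x += [np.log(min(max(t, lo), hi)) for t in src]
        return np.array(x)

    def unpack(self, x):
        kappa = float(np.exp(x[0]))
        k = len(self.classes)
        omegas = np.exp(x[1:1 + k])
        omega_by_class = {}
        for cls_group, w in zip(self.classes, omegas):
            for cls in cls_group:
                omega_by_class[cls] = float(w)
        lengths = np.exp(x[1 + k:]) if self.branch_nodes else None
        return kappa, omega_by_class, lengths

    def __call__(self, x):
        kappa, omega_by_class, lengths = self.unpack(x)
        if lengths is not None:
            for node, t in zip(self.branch_nodes, lengths):
                node.length = float(t)
        params = CodonModelParams(kappa=kappa, omega_by_class=omega_by_class,
                                  codon_freqs=self.freqs,
                                  freq_model=self.freq_model)
        val = -self.engine.lnl(params)
        if not np.isfinite(val):
            val = 1e300
        if val < self.best[0]:
            self.best = (val, x.copy())
        return val


def _optimize(obj: _Objective, x0: np.ndarray, config: FitConfig,
              rng: np.random.Generator) -> tuple:
    """L-BFGS-B from x0 plus optional seeded random restarts.

    Each start is polished by restarting from its own optimum until the
    gain drops below the lnL tolerance, so nested fits are equally
    converged and the LRT statistic is not inflated by one model
    stopping earlier than the other.
    """
    starts = [x0]
    bounds = obj.bounds()
    for _ in range(config.n_restarts):
        jitter = rng.normal(0.0, 0.5, size=len(x0))
        xr = np.clip(x0 + jitter, [b[0] for b in bounds], [b[1] for b in bounds])
        starts.append(xr)
    converged = False
    for xs in starts:
        prev = obj(xs)
        options = {"ftol": config.lnl_tol / max(1.0, abs(prev)),
                   "gtol": 1e-8, "maxiter": config.max_iter}
        for _ in range(4):
            res = minimize(obj, xs, method="L-BFGS-B", bounds=bounds,
                           options=options)
            converged = converged or bool(res.success)
            if prev - res.fun < config.lnl_tol:
                break
            prev, xs = res.fun, res.x
    best_val, best_x = obj.best
    return best_x, -best_val, converged


def _gene_rng(config: FitConfig, gene_id: str) -> np.random.Generator:
    # stable per-gene stream: restarts do not depend on fit order
    mix = zlib.crc32(gene_id.encode()) & 0x7FFFFFFF
    return np.random.default_rng((config.seed, mix))


def fit_gene(aln: CodonAlignment, tree: TaggedTree,
             config: FitConfig | None = None) -> GeneFitResult:
    """Fit ORM and TRM to one gene and test the domestication contrast.

    The tree must carry at least one WILD and one DOMESTIC branch.
    Genes whose fitted contrast has essentially no synonymous (or no
    nonsynonymous) divergence are flagged extreme; downstream summaries
    keep such genes only when the test is significant.
    """
    config = config or FitConfig()
    classes = tree.branch_classes()
    if classes != {WILD, DOMESTIC}:
        raise ValueError(
            f"{aln.gene_id}: tree needs both WILD and DOMESTIC branches, "
            f"found {sorted(classes)}")
    rng = _gene_rng(config, aln.gene_id)
    freqs = codon_frequencies(aln, config.freq_model)

    work_tree = tree.unrooted()
    engine = PruningLikelihood(aln, work_tree)

    # --- ORM: shared omega -------------------------------------------
    orm = _Objective(engine, work_tree, freqs, config.freq_model,
                     classes=[(WILD, DOMESTIC)], config=config)
    x0 = orm.pack(kappa=2.0, omegas=[0.4])
    x_orm, lnl_orm, conv_orm = _optimize(orm, x0, config, rng)
    kappa_orm, omega_shared_map, lengths_orm = orm.unpack(x_orm)
    omega_shared = omega_shared_map[WILD]

    # --- TRM: per-class omegas, started at the ORM optimum -----------
    trm = _Objective(engine, work_tree, freqs, config.freq_model,
                     classes=[(WILD,), (DOMESTIC,)], config=config)
    lengths = list(lengths_orm) if lengths_orm is not None else None
    x1 = trm.pack(kappa=kappa_orm, omegas=[omega_shared, omega_shared],
                  lengths=lengths)
    x_trm, lnl_trm, conv_trm = _optimize(trm, x1, config, rng)
    kappa_trm, omega_by_class, lengths_trm = trm.unpack(x_trm)
    lnl_trm = max(lnl_trm, lnl_orm)  # nesting holds up to optimizer noise

    stat, p = lrt_pvalue(lnl_orm, lnl_trm)
    significant = p < config.p_threshold

    extreme = _extreme_flag(work_tree, trm, x_trm, freqs, config)

    return GeneFitResult(
        gene_id=aln.gene_id,
        lnL_ORM=lnl_orm, lnL_TRM=lnl_trm,
        omega_shared=omega_shared,
        omega_W=omega_by_class[WILD], omega_D=omega_by_class[DOMESTIC],
        kappa_ORM=kappa_orm, kappa_TRM=kappa_trm,
        lrt_stat=stat, df=1, p_value=p,
        extreme_flag=extreme, significant=significant,
        converged=conv_orm and conv_trm,
        n_codons=aln.n_codons,
    )


def _extreme_flag(tree: TaggedTree, obj: _Objective, x: np.ndarray,
                  freqs: np.ndarray, config: FitConfig) -> str:
    """Flag fits whose contrast rests on ~zero syn or nonsyn divergence."""
    kappa, omega_by_class, lengths = obj.unpack(x)
    if lengths is not None:
        for node, t in zip(obj.branch_nodes, lengths):
            node.length = float(t)
    params = CodonModelParams(kappa=kappa, omega_by_class=omega_by_class,
                              codon_freqs=freqs, freq_model=config.freq_model)
    floor = config.syn_divergence_floor
    wmin, wmax = config.omega_bounds
    for cls in (WILD, DOMESTIC):
        rho_syn = synonymous_rate_fraction(params, cls)
        total = tree.total_length(cls)
        if total * rho_syn < floor or omega_by_class[cls] >= wmax * (1 - 1e-9):
            return EXTREME_NO_SYN
        if total * (1.0 - rho_syn) < floor or omega_by_class[cls] <= wmin * (1 + 1e-9):
            return EXTREME_NO_NONSYN
    return EXTREME_NONE


def apply_bh(results: list, alpha: float) -> None:
    """Benjamini–Hochberg re-flagging of ``significant`` across genes."""
    from scipy.stats import false_discovery_control

    if not results:
        return
    p = np.array([r.p_value for r in results])
    q = false_discovery_control(p, method="bh")
    for r, qv in zip(results, q):
        r.significant = bool(qv < alpha)
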