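"""Event-level simulation of codon evolution and whole synthetic studies.

Sequences evolve along each branch by exact (Gillespie) simulation under
that branch's class rate matrix, so every substitution event is logged
with its branch, site and codon change.  The logged history serves as the
ground truth for parameter-recovery and substitution-counting tests.

A "study" bundles several species, each with its own effective
population size (Ne) and a set of genes: a configurable fraction of
genes evolve under a two-ratios model whose domestic/wild omega contrast
grows with Ne through a monotone log-linear effect map, emulating the
hypothesis that larger populations make selection more efficient after
domestication.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .alignment import CodonAlignment
from .codes import GeneticCode, STANDARD_CODE
from .codon_model import CodonModelParams, build_rate_matrix
from .trees import DOMESTIC, WILD, Node, TaggedTree


@dataclass
class SimulationConfig:
    """One gene's simulation settings."""

    n_wild: int = 3
    n_domestic: int = 3
    branch_length: float = 0.1
    kappa: float = 2.0
    omega_W: float = 0.2
    omega_D: float = 0.2
    freq_model: str = "EQUAL"
    codon_freqs: np.ndarray | None = None
    n_codons: int = 300
    seed: int = 0
    gene_id: str = "gene"

    def __post_init__(self):
        if self.n_codons < 1:
            raise ValueError("n_codons must be >= 1")
        if self.n_wild < 1 or self.n_domestic < 1:
            raise ValueError("need at least one wild and one domestic taxon")
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")
        if self.branch_length < 0 or self.omega_W < 0 or self.omega_D < 0:
            raise ValueError("rates and lengths must be non-negative")
        if self.seed is None:
            raise ValueError("seed is mandatory")


@dataclass
class Event:
    branch_id: str
    site: int          # 1-based codon column
    from_codon: str
    to_codon: str
    synonymous: bool


@dataclass
class TrueHistory:
    """Ground truth of one simulated gene."""

    gene_id: str
    model: str                   # "ORM" or "TRM"
    omega_W: float
    omega_D: float
    events: list
    node_states: dict            # branch_id/"root" -> codon state array

    def events_on(self, branch_id: str) -> list:
        return [e for e in self.events if e.branch_id == branch_id]


def _ladder(names: list, length: float, branch_class: str) -> Node:
    """Pectinate subtree over the given leaves; all branches one class."""
    node = Node(name=names[0], length=length, branch_class=branch_class)
    for name in names[1:]:
        leaf = Node(name=name, length=length, branch_class=branch_class)
        node = Node(length=length, branch_class=branch_class,
                    children=[node, leaf])
    return node


def build_study_tree(n_wild: int, n_domestic: int,
                     branch_length: float) -> TaggedTree:
    """Wild individuals and a fully DOMESTIC-tagged domestic clade.

    The tree is built in unrooted form (trifurcating basal node inside
    the wild group) so that every branch is identifiable in the ML fit;
    the domestic clade's stem and internal branches are DOMESTIC — the
    domestication event sits at the base of that clade.
    """
    dom = _ladder([f"d{i+1}" for i in range(n_domestic)],
                  branch_length, DOMESTIC)
    wild_names = [f"w{i+1}" for i in range(n_wild)]
    if n_wild == 1:
        basal_children = [Node(name=wild_names[0], length=branch_length,
                               branch_class=WILD), dom]
    else:
        wild = _ladder(wild_names, branch_length, WILD)
        basal_children = list(wild.children) + [dom]
    return TaggedTree(Node(children=basal_children))


def _gillespie_branch(states: np.ndarray, Q: np.ndarray, t: float,
                      branch_id: str, rng: np.random.Generator,
                      code: GeneticCode, events: list) -> np.ndarray:
    """Evolve every site independently for time t; append logged events."""
    exit_rate = -np.diag(Q)
    jump = Q.copy()
    np.fill_diagonal(jump, 0.0)
    row_sums = jump.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        jump = np.where(row_sums[:, None] > 0, jump / row_sums[:, None], 0.0)
    out = states.copy()
    n_states = Q.shape[0]
    for site in range(out.size):
        clock = 0.0
        s = int(out[site])
        while True:
            rate = exit_rate[s]
            if rate <= 0:
                break
            clock += rng.exponential(1.0 / rate)
            if clock >= t:
                break
            s_new = int(rng.choice(n_states, p=jump[s]))
            ci, cj = code.sense_codons[s], code.sense_codons[s_new]
            events.append(Event(
                branch_id=branch_id, site=site + 1,
                from_codon=ci, to_codon=cj,
                synonymous=code.translate(ci) == code.translate(cj)))
            s = s_new
        out[site] = s
    return out


def simulate_alignment(config: SimulationConfig,
                       tree: TaggedTree | None = None,
                       ) -> tuple:
    """Simulate one gene; returns (CodonAlignment, TaggedTree, TrueHistory).

    The root codon sequence is drawn from the stationary frequencies and
    evolved down the (possibly caller-supplied) tagged tree.
    """
    code = STANDARD_CODE
    rng = np.random.default_rng(config.seed)
    if tree is None:
        tree = build_study_tree(config.n_wild, config.n_domestic,
                                config.branch_length)
    if config.codon_freqs is not None:
        pi = np.asarray(config.codon_freqs, float)
    else:
        pi = np.full(code.n_states, 1.0 / code.n_states)
    params = CodonModelParams(
        kappa=config.kappa,
        omega_by_class={WILD: max(config.omega_W, 1e-300),
                        DOMESTIC: max(config.omega_D, 1e-300)},
        codon_freqs=pi, freq_model=config.freq_model)
    Q = {cls: build_rate_matrix(params, cls) for cls in (WILD, DOMESTIC)}
    if config.omega_W == 0:
        Q[WILD] = _zero_nonsyn(Q[WILD], code)
    if config.omega_D == 0:
        Q[DOMESTIC] = _zero_nonsyn(Q[DOMESTIC], code)

    events: list = []
    node_states = {}
    root_states = rng.choice(code.n_states, size=config.n_codons, p=pi)
    node_states["root"] = root_states

    def descend(node, states):
        for child in node.children:
            child_states = _gillespie_branch(
                states, Q[child.branch_class], child.length,
                child.branch_id, rng, code, events)
            node_states[child.branch_id] = child_states
            descend(child, child_states)

    descend(tree.root, root_states)

    taxa, seqs = [], []
    for leaf in tree.leaves:
        taxa.append(leaf.name)
        seqs.append("".join(code.sense_codons[s]
                            for s in node_states[leaf.branch_id]))
    aln = CodonAlignment(config.gene_id, taxa, seqs)
    model = "ORM" if config.omega_W == config.omega_D else "TRM"
    history = TrueHistory(config.gene_id, model, config.omega_W,
                          config.omega_D, events, node_states)
    return aln, tree, history


def _zero_nonsyn(Q: np.ndarray, code: GeneticCode) -> np.ndarray:
    """Exact omega=0 limit: remove all nonsynonymous flux."""
    from .codon_model import _pair_structure

    I, J, _, ns = _pair_structure(code)
    Q = Q.copy()
    Q[I[ns], J[ns]] = 0.0
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


# ---------------------------------------------------------------------
# whole-study simulation


@dataclass
class StudyConfig:
    """Multi-species synthetic study with an Ne-linked domestication effect.

    ``effect_slope`` is beta in E[log(omega_D/omega_W)] =
    beta * log10(Ne / Ne_min) for TRM genes; zero slope gives a null
    study.  ``noise_scale`` is the s.d. of lognormal noise on the ratio.
    """

    species_ne: dict = field(default_factory=lambda: {
        f"sp{i+1}": ne for i, ne in
        enumerate(np.geomspace(1e4, 1e5, 8).round())})
    genes_per_species: int = 100
    fraction_trm: float = 0.3
    effect_slope: float = 0.5
    noise_scale: float = 0.15
    omega_w_median: float = 0.2
    omega_w_sigma: float = 0.3
    n_codons: int = 300
    n_wild: int = 3
    n_domestic: int = 3
    branch_length: float = 0.1
    length_jitter_sigma: float = 0.2
    kappa: float = 2.0
    seed: int = 0

    def __post_init__(self):
        if len(self.species_ne) < 3:
            raise ValueError("a study needs at least 3 species")
        if self.genes_per_species < 1:
            raise ValueError("genes_per_species must be >= 1")
        if not 0.0 <= self.fraction_trm <= 1.0:
            raise ValueError("fraction_trm must be in [0, 1]")
        ne = list(self.species_ne.values())
        if any(v <= 0 for v in ne):
            raise ValueError("Ne values must be positive")
        if self.effect_slope != 0.0 and len(set(ne)) == 1:
            raise ValueError(
                "all Ne equal: a nonzero effect slope is unidentifiable")


@dataclass
class SpeciesData:
    species: str
    ne_recent: float
    alignments: list
    trees: list
    histories: list


@dataclass
class StudyBundle:
    config: StudyConfig
    species_data: dict          # species -> SpeciesData
    true_effects: dict          # species -> expected log(omega_D/omega_W)

    @property
    def ne_records(self) -> dict:
        return {sp: d.ne_recent for sp, d in self.species_data.items()}


def simulate_study(config: StudyConfig) -> StudyBundle:
    """Simulate every gene of every species; deterministic given the seed."""
    rng = np.random.default_rng(config.seed)
    ne_min = min(config.species_ne.values())
    bundle = {}
    effects = {}
    for species, ne in config.species_ne.items():
        effect = config.effect_slope * np.log10(ne / ne_min)
        effects[species] = float(effect)
        alns, trees, hists = [], [], []
        for g in range(config.genes_per_species):
            gene_id = f"{species}_g{g+1:04d}"
            omega_w = float(config.omega_w_median
                            * np.exp(rng.normal(0.0, config.omega_w_sigma)))
            if rng.random() < config.fraction_trm:
                log_ratio = effect + rng.normal(0.0, config.noise_scale)
                omega_d = float(omega_w * np.exp(log_ratio))
            else:
                omega_d = omega_w
            tree = build_study_tree(config.n_wild, config.n_domestic,
                                    config.branch_length)
            if config.length_jitter_sigma > 0:
                for node in tree.branches:
                    node.length *= float(np.exp(rng.normal(
                        0.0, config.length_jitter_sigma)))
            gene_cfg = SimulationConfig(
                n_wild=config.n_wild, n_domestic=config.n_domestic,
                branch_length=config.branch_length, kappa=config.kappa,
                omega_W=omega_w, omega_D=omega_d,
                n_codons=config.n_codons,
                seed=int(rng.integers(0, 2**31 - 1)), gene_id=gene_id)
            aln, tree, hist = simulate_alignment(gene_cfg, tree=tree)
            alns.append(aln)
            trees.append(tree)
            hists.append(hist)
        bundle[species] = SpeciesData(species, float(ne), alns, trees, hists)
    return StudyBundle(config, bundle, effects)
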