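"""Selection-dynamics taxonomy and per-species summaries.

Each gene with a significant wild/domestic contrast falls into exactly
one of six directions of selection-pressure change, determined by the
ordering of the wild ratio (W), the domestic ratio (D) and 1:

* RPR - relaxed purifying selection        (1 > D > W)
* IPR - intensified purifying selection    (1 > W > D)
* IPS - intensified positive selection     (D > W > 1)
* RPS - relaxed positive selection         (W > D > 1)
* PST - transition to positive selection   (W < 1 < D)
* PRT - transition to purifying selection  (D < 1 < W)

Genes without a significant contrast, or with ratios tied with each
other or with 1, are UN (unchanged).  The per-species accumulation
metric is the ratio of mean domestic over mean wild omega across
significant genes, together with the analogous radical and conservative
substitution-count ratios.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from .parsimony import CONSERVATIVE, RADICAL, SYNONYMOUS, LineageMutationCounts
from .trees import DOMESTIC, WILD

RPR, IPR, IPS, RPS, PST, PRT, UN = "RPR", "IPR", "IPS", "RPS", "PST", "PRT", "UN"
CATEGORIES = (UN, PST, IPS, RPR, RPS, IPR, PRT)   # canonical column order
NON_UN_CATEGORIES = (PST, IPS, RPR, RPS, IPR, PRT)


def classify_dynamics(omega_W: float, omega_D: float, significant: bool,
                      tol: float = 1e-9) -> str:
    """Place one gene in the selection-dynamics taxonomy.

    Non-significant genes are UN regardless of the point estimates;
    ratios within ``tol`` of each other or of 1 are treated as ties and
    also give UN.
    """
    if omega_W <= 0 or omega_D <= 0:
        raise ValueError(f"omega values must be positive "
                         f"(got W={omega_W}, D={omega_D})")
    if not significant:
        return UN
    if (abs(omega_D - omega_W) <= tol
            or abs(omega_W - 1.0) <= tol or abs(omega_D - 1.0) <= tol):
        return UN
    if omega_D < 1.0 and omega_W < 1.0:
        return RPR if omega_D > omega_W else IPR
    if omega_D > 1.0 and omega_W > 1.0:
        return IPS if omega_D > omega_W else RPS
    return PST if omega_D > 1.0 else PRT


@dataclass
class SpeciesSummary:
    species: str
    n_genes_total: int
    n_genes_significant: int
    mean_omega_D: float = math.nan
    mean_omega_W: float = math.nan
    ratio_omega: float = math.nan
    ratio_radical: float = math.nan
    ratio_conservative: float = math.nan
    dynamics_counts: dict = field(default_factory=dict)
    undefined: set = field(default_factory=set)   # names of undefined metrics

    def metric(self, name: str) -> float:
        if name in self.undefined:
            return math.nan
        return getattr(self, name)


def summarize_species(results: list, counts: list, species: str,
                      dynamics_tol: float = 1e-9) -> SpeciesSummary:
    """Aggregate per-gene fits and substitution counts for one species.

    ``results`` and ``counts`` are parallel lists over the same genes.
    Mean omegas are unweighted arithmetic means over significant genes
    (extreme-flagged genes therefore enter only when significant, and
    capped extreme estimates enter the mean as capped); the radical and
    conservative ratios are quotients of substitution-count sums over
    significant genes.
    """
    if len(results) != len(counts):
        raise ValueError(f"{species}: {len(results)} fit results but "
                         f"{len(counts)} count records")
    summary = SpeciesSummary(species=species, n_genes_total=len(results),
                             n_genes_significant=0)
    dyn = {cat: 0 for cat in CATEGORIES}
    sig = [r for r in results if r.significant]
    summary.n_genes_significant = len(sig)

    for r in results:
        dyn[classify_dynamics(r.omega_W, r.omega_D, r.significant,
                              dynamics_tol)] += 1
    summary.dynamics_counts = dyn

    if sig:
        summary.mean_omega_W = sum(r.omega_W for r in sig) / len(sig)
        summary.mean_omega_D = sum(r.omega_D for r in sig) / len(sig)
        if summary.mean_omega_W > 0:
            summary.ratio_omega = summary.mean_omega_D / summary.mean_omega_W
        else:
            summary.undefined.add("ratio_omega")
    else:
        summary.undefined |= {"mean_omega_W", "mean_omega_D", "ratio_omega"}

    total = LineageMutationCounts()
    for r, c in zip(results, counts):
        if r.significant:
            total = total + c
    for name, kind in (("ratio_radical", RADICAL),
                       ("ratio_conservative", CONSERVATIVE)):
        w = total.get(WILD, kind)
        d = total.get(DOMESTIC, kind)
        if w > 0:
            setattr(summary, name, d / w)
        else:
            summary.undefined.add(name)
    return summary


def dynamics_table(summaries: list) -> pd.DataFrame:
    """Cross-species gene counts per dynamics category.

    Rows are species; columns follow the canonical order
    UN, PST, IPS, RPR, RPS, IPR, PRT.  Row sums equal each species'
    total gene count.
    """
    if not summaries:
        raise ValueError("need at least one species summary")
    names = [s.species for s in summaries]
    if len(set(names)) != len(names):
        raise ValueError("duplicate species in summaries")
    rows = {s.species: [s.dynamics_counts.get(cat, 0) for cat in CATEGORIES]
            for s in summaries}
    return pd.DataFrame.from_dict(rows, orient="index",
                                  columns=list(CATEGORIES))


def species_table(summaries: list) -> pd.DataFrame:
    """Per-species summary table (one row per species)."""
    rows = []
    for s in summaries:
        rows.append({
            "species": s.species,
            "n_genes_total": s.n_genes_total,
            "n_genes_significant": s.n_genes_significant,
            "mean_omega_D": s.metric("mean_omega_D"),
            "mean_omega_W": s.metric("mean_omega_W"),
            "ratio_omega": s.metric("ratio_omega"),
            "ratio_radical": s.metric("ratio_radical"),
            "ratio_conservative": s.metric("ratio_conservative"),
        })
    return pd.DataFrame(rows)
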