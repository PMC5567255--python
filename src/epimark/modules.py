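"""Co-expression-module contingency analysis.

A module is the neighbourhood of an anchor gene in a co-expression network.
Each member carries two flags: expressed (FPKM above an activity cutoff) and
marked (a mark peak associated under the TSS window rule).  The module's
marked/unmarked split within its expressed or unexpressed subset is tested
against the genome-wide marked/unmarked background with a two-sided Fisher
exact test, implemented here with log-space hypergeometric point
probabilities and the minimum-likelihood two-sided convention.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy.stats import hypergeom

from .core import GeneModel, Peak

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class Contingency2x2:
    """Counts [[a, b], [c, d]]: row 1 the focal set (marked, unmarked),
    row 2 the background (marked, unmarked)."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("negative count in contingency table")

    @property
    def table(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]])


@dataclass
class ModuleMember:
    gene_id: str
    edge_sign: str  # "positive" | "negative"
    expressed: bool
    marked: bool


@dataclass
class CoexpressionModule:
    anchor: str
    members: List[ModuleMember]

    def subset(self, which: str) -> List[ModuleMember]:
        if which == "expressed":
            return [m for m in self.members if m.expressed]
        if which == "unexpressed":
            return [m for m in self.members if not m.expressed]
        raise ValueError(f"unknown subset {which!r}")


def fisher_exact_two_sided(t: Contingency2x2) -> float:
    """Two-sided Fisher exact p-value by minimum-likelihood summation.

    With margins fixed, the first cell follows a hypergeometric law; the
    two-sided p is the sum of point probabilities of every table whose
    probability does not exceed the observed one (up to a 1e-7 relative
    tolerance for floating-point safety).  Probabilities are evaluated in
    log space so large genome-scale margins are exact to double precision.
    Any zero margin makes every table equally (un)informative: p = 1.
    """
    a, b, c, d = t.a, t.b, t.c, t.d
    n = a + b + c + d
    r1, c1 = a + b, a + c
    if r1 == 0 or c1 == 0 or r1 == n or c1 == n:
        log.warning("degenerate margin in contingency table; p = 1")
        return 1.0
    lo = max(0, r1 + c1 - n)
    hi = min(r1, c1)
    support = np.arange(lo, hi + 1)
    logpmf = hypergeom.logpmf(support, n, c1, r1)
    log_obs = logpmf[a - lo]
    keep = logpmf <= log_obs + 1e-7
    # log-sum-exp over the kept tables
    m = logpmf[keep].max()
    p = float(np.exp(m) * np.exp(logpmf[keep] - m).sum())
    return min(1.0, p)


def build_module(
    anchor: str,
    edges: pd.DataFrame,
    expr: pd.DataFrame,
    peaks: Sequence[Peak],
    genes: Mapping[str, GeneModel],
    sample: str,
    active_cutoff: float = 0.0,
    window_up: int = 1000,
    positive_only: bool = False,
) -> CoexpressionModule:
    """Assemble the co-expression module of ``anchor`` from an edge list.

    Edge list columns: gene_a, gene_b, sign ("positive"/"negative").  The
    expressed flag is FPKM > cutoff in ``sample``; the marked flag is having
    >=1 peak centre inside the gene's [TSS - window_up, end) span.
    """
    mask = (edges["gene_a"] == anchor) | (edges["gene_b"] == anchor)
    sub = edges[mask]
    if sub.empty:
        raise KeyError(f"anchor {anchor} not present in edge list")
    trees: Dict[str, IntervalTree] = {}
    for g in genes.values():
        w = g.mark_window(window_up)
        trees.setdefault(g.chrom, IntervalTree()).addi(w.start, w.end, g.gene_id)
    marked_ids = set()
    for p in peaks:
        tree = trees.get(p.chrom)
        if tree is not None:
            marked_ids.update(h.data for h in tree[p.centre])
    members = []
    for _, row in sub.iterrows():
        other = row["gene_b"] if row["gene_a"] == anchor else row["gene_a"]
        sign = row.get("sign", "positive")
        if positive_only and sign != "positive":
            continue
        fpkm = float(expr.loc[other, sample]) if other in expr.index else 0.0
        members.append(
            ModuleMember(other, sign, fpkm > active_cutoff, other in marked_ids)
        )
    members.sort(key=lambda m: m.gene_id)
    return CoexpressionModule(anchor, members)


def module_contingency(
    module: CoexpressionModule,
    subset: str,
    genome_marked: int,
    genome_unmarked: int,
) -> Contingency2x2:
    """2x2 table: module subset (marked/unmarked) vs genome background.

    Background counts are used as given (module members are not subtracted;
    at genome scale the correction is negligible).
    """
    sub = module.subset(subset)
    if not sub:
        raise ValueError(f"module subset {subset!r} is empty")
    marked = sum(m.marked for m in sub)
    return Contingency2x2(marked, len(sub) - marked, genome_marked, genome_unmarked)


def module_report(module: CoexpressionModule) -> Dict[str, float]:
    """Summary fractions of a module with their numerators/denominators.

    - frac_expressed_marked: marked among expressed members
    - frac_unmarked_unexpressed: unexpressed among unmarked members
    - frac_unexpressed: unexpressed among all members
    Zero denominators yield NaN.
    """
    def frac(num: int, den: int, key: str, out: Dict[str, float]) -> None:
        out[key] = num / den if den else float("nan")
        out[f"{key}_n"] = num
        out[f"{key}_d"] = den

    expressed = module.subset("expressed")
    unmarked = [m for m in module.members if not m.marked]
    out: Dict[str, float] = {}
    frac(sum(m.marked for m in expressed), len(expressed), "frac_expressed_marked", out)
    frac(sum(not m.expressed for m in unmarked), len(unmarked), "frac_unmarked_unexpressed", out)
    frac(sum(not m.expressed for m in module.members), len(module.members), "frac_unexpressed", out)
    return out
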