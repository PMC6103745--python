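"""Single-sample gene-set enrichment (ssGSEA-style) and EMT classification.

Each sample is scored independently: genes are ranked by expression
(descending, ties broken by stable gene order), and the enrichment score
is the sum over all rank positions of the difference between the
weighted in-set cumulative fraction and the uniform out-of-set
cumulative fraction,

    ES = sum_i [ P_in(i) - P_out(i) ],
    P_in(i)  = sum_{g in G, rank(g) <= i} w_g^alpha / sum_{g in G} w_g^alpha,
    P_out(i) = #{g not in G, rank(g) <= i} / (N - |G|),

with w_g the rank value (top-ranked gene has weight N) and alpha = 0.25.
An epithelial-to-mesenchymal-transition (EMT) score combines an UP and a
DOWN signature as the difference of their enrichment scores; samples in
the extreme quantiles of the combined score are classified as
mesenchymal (top) or epithelial (bottom).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GeneSet",
    "ssgsea_score",
    "combined_signature_score",
    "classify_extremes",
]

logger = logging.getLogger(__name__)


@dataclass
class GeneSet:
    """A named gene set with an optional UP/DOWN direction tag."""

    name: str
    members: tuple[str, ...]
    direction: str = "NA"
    description: str = ""

    def __post_init__(self) -> None:
        members = tuple(dict.fromkeys(self.members))  # dedupe, keep order
        if len(members) < len(self.members):
            logger.warning("gene set %s: duplicate members removed", self.name)
        object.__setattr__(self, "members", members)
        if not self.members:
            raise ValueError(f"gene set {self.name!r} is empty")
        if self.direction not in ("UP", "DOWN", "NA"):
            raise ValueError(f"direction must be UP/DOWN/NA, got {self.direction!r}")

    def __len__(self) -> int:
        return len(self.members)


def _validate_expression(expr: pd.DataFrame) -> None:
    if expr.index.has_duplicates:
        raise ValueError("expression matrix has duplicate gene ids")
    if not np.isfinite(expr.to_numpy(dtype=float)).all():
        raise ValueError("expression matrix contains non-finite values")


def ssgsea_score(expr: pd.DataFrame, gene_set: GeneSet, alpha: float = 0.25) -> pd.Series:
    """Per-sample weighted running-sum enrichment score for one gene set.

    Depends only on each sample's expression *ranks* (invariant under
    strictly increasing transforms).  Set members absent from the matrix
    are dropped with a warning; a set covering every gene is an error
    because the out-of-set distribution is then undefined.
    """
    _validate_expression(expr)
    present = [g for g in gene_set.members if g in expr.index]
    dropped = len(gene_set) - len(present)
    if dropped:
        logger.warning("gene set %s: %d members absent from matrix", gene_set.name, dropped)
    if not present:
        raise ValueError(f"no member of gene set {gene_set.name!r} is in the matrix")
    n_genes = expr.shape[0]
    if len(present) >= n_genes:
        raise ValueError("gene set covers all genes; enrichment undefined")
    in_set = expr.index.isin(present)
    values = expr.to_numpy(dtype=float)
    scores = {}
    for j, sample in enumerate(expr.columns):
        # Descending stable sort: ties resolved by original gene order.
        order = np.argsort(-values[:, j], kind="stable")
        member = in_set[order]
        weights = (n_genes - np.arange(n_genes)).astype(float) ** alpha  # rank values
        w_in = np.where(member, weights, 0.0)
        p_in = np.cumsum(w_in) / w_in.sum()
        p_out = np.cumsum(~member) / (n_genes - member.sum())
        scores[sample] = float(np.sum(p_in - p_out))
    return pd.Series(scores, name=gene_set.name)


def combined_signature_score(
    expr: pd.DataFrame,
    up: GeneSet,
    down: GeneSet,
    alpha: float = 0.25,
) -> pd.Series:
    """Combined signature score: ES(UP) - ES(DOWN) per sample.

    Overlapping members are removed from both sets with a warning before
    scoring; if de-overlapping empties either set this is an error.
    """
    shared = set(up.members) & set(down.members)
    if shared:
        logger.warning(
            "UP/DOWN signatures share %d genes; removed from both before scoring", len(shared)
        )
        up_members = tuple(g for g in up.members if g not in shared)
        down_members = tuple(g for g in down.members if g not in shared)
        if not up_members or not down_members:
            raise ValueError("UP and DOWN signatures are identical after de-overlap")
        up = GeneSet(up.name, up_members, up.direction)
        down = GeneSet(down.name, down_members, down.direction)
    score = ssgsea_score(expr, up, alpha) - ssgsea_score(expr, down, alpha)
    score.name = "combined"
    return score


def classify_extremes(scores: pd.Series, fraction: float = 0.2) -> pd.Series:
    """Label extreme-score samples: top tail mesenchymal, bottom epithelial.

    Exactly ``k = floor(fraction * n)`` samples per tail (the remainder
    are ``intermediate``).  Ties are broken by stable sample order, and
    the two tails are guaranteed disjoint since ``fraction <= 0.5``.
    """
    if not 0 < fraction <= 0.5:
        raise ValueError("fraction must be in (0, 0.5]")
    n = len(scores)
    if n < 2:
        raise ValueError("need at least two samples to classify")
    k = int(np.floor(fraction * n))
    if k < 1:
        raise ValueError(f"fraction {fraction} selects zero samples out of {n}")
    order = np.argsort(-scores.to_numpy(dtype=float), kind="stable")
    labels = pd.Series("intermediate", index=scores.index, name="class")
    labels.iloc[order[:k]] = "mesenchymal"
    labels.iloc[order[n - k:]] = "epithelial"
    return labels
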