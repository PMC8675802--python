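"""Model/results interface over the full interaction-scoring procedure.

:class:`GeneInteractionModel` is constructed from an expression matrix
(or a plain DataFrame) and holds everything that is fixed before
estimation: the gene set, the RBM hyperparameters, the normalization
policy.  Calling :meth:`~GeneInteractionModel.fit` trains one bridged RBM
pair per unordered gene pair and returns a
:class:`GeneInteractionResults` carrying the per-pair strengths and
errors, the theta-filtered candidate set, and the oriented network, with
``summary()``, comparison and plotting conveniences.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix, maxmin_normalize, select_genes
from .network import (
    DEFAULT_THETA,
    InteractionCandidate,
    NetworkComparison,
    RegulatoryNetwork,
    build_network,
    candidates_from_results,
    compare_networks,
    edges_vs_threshold,
    filter_interactions,
)
from .paired_rbm import PairResult, RBMPairConfig, pair_seed_sequence, train_pair

logger = logging.getLogger(__name__)

__all__ = ["GeneInteractionModel", "GeneInteractionResults"]


class GeneInteractionModel:
    """Pairwise RBM interaction model over one expression matrix.

    Parameters
    ----------
    data
        Raw expression matrix (genes x samples).  Rows are rescaled to
        [0, 1] per gene before training; direction of regulation is always
        decided on the raw rows.
    config
        RBM pair hyperparameters; ``config.seed`` is the global seed from
        which each pair derives its own stream.
    genes
        Optional ordered subset of gene ids to model (selection happens
        before normalization, so the subset defines its own row ranges).
    """

    def __init__(
        self,
        data: ExpressionMatrix,
        config: RBMPairConfig | None = None,
        genes: Sequence[str] | None = None,
        condition_label: str = "",
    ) -> None:
        if genes is not None:
            data = select_genes(data, genes)
        if data.n_genes < 2:
            raise ValueError("need at least two genes to score interactions")
        self.raw = data
        self.normalized = maxmin_normalize(data)
        self.config = config or RBMPairConfig()
        self.condition_label = condition_label

    @classmethod
    def from_dataframe(
        cls,
        frame: pd.DataFrame,
        config: RBMPairConfig | None = None,
        phenotype: dict[str, str] | None = None,
        genes: Sequence[str] | None = None,
        condition_label: str = "",
    ) -> "GeneInteractionModel":
        """Build from a genes x samples DataFrame."""
        return cls(
            ExpressionMatrix(frame.copy(), phenotype or {}),
            config,
            genes,
            condition_label,
        )

    @property
    def gene_ids(self) -> list[str]:
        return self.raw.gene_ids

    def pairs(self) -> list[tuple[str, str]]:
        """Unordered gene pairs in lexicographic order."""
        ids = sorted(self.gene_ids)
        return [(a, b) for i, a in enumerate(ids) for b in ids[i + 1 :]]

    def fit(self, theta: float = DEFAULT_THETA, seed: int | None = None
            ) -> "GeneInteractionResults":
        """Train all pairs, filter at ``theta`` and orient the survivors.

        ``seed`` overrides ``config.seed``.  Each pair's randomness comes
        from a stream derived from the global seed and the two gene ids,
        so results do not depend on iteration order.
        """
        config = self.config if seed is None else replace(self.config, seed=seed)
        results: list[PairResult] = []
        for gene_a, gene_b in self.pairs():
            rng = np.random.default_rng(pair_seed_sequence(config.seed, gene_a, gene_b))
            result = train_pair(
                self.normalized.row(gene_a),
                self.normalized.row(gene_b),
                config,
                gene_a=gene_a,
                gene_b=gene_b,
                rng=rng,
            )
            logger.debug(
                "pair %s-%s: gap=%.4g err=(%.4g, %.4g) epochs=%d converged=%s",
                gene_a, gene_b, result.strength_gap, result.error_a, result.error_b,
                result.epochs_run, result.converged,
            )
            results.append(result)
        return GeneInteractionResults(model=self, pair_results=results, theta=theta,
                                      seed=config.seed)


@dataclass
class GeneInteractionResults:
    """Fitted interaction scores and the network they induce."""

    model: GeneInteractionModel
    pair_results: list[PairResult]
    theta: float
    seed: int

    def __post_init__(self) -> None:
        self.candidates: list[InteractionCandidate] = candidates_from_results(
            self.pair_results
        )
        self.accepted: list[InteractionCandidate] = filter_interactions(
            self.candidates, self.theta
        )
        self.network: RegulatoryNetwork = build_network(
            self.accepted,
            self.model.raw,
            condition_label=self.model.condition_label,
            theta=self.theta,
        )

    def candidates_frame(self) -> pd.DataFrame:
        """All trained pairs as a DataFrame (one row per unordered pair)."""
        rows = [
            {
                "gene_a": r.gene_a,
                "gene_b": r.gene_b,
                "strength_a": r.strength_a,
                "strength_b": r.strength_b,
                "error_a": r.error_a,
                "error_b": r.error_b,
                "epochs_run": r.epochs_run,
                "converged": r.converged,
                "matched_units": r.matched_units,
            }
            for r in self.pair_results
        ]
        return pd.DataFrame(rows)

    def edges_frame(self) -> pd.DataFrame:
        rows = [
            {
                "regulator": e.regulator,
                "target": e.target,
                "strength": e.strength,
                "tie": e.tie,
            }
            for e in self.network.edges
        ]
        return pd.DataFrame(rows, columns=["regulator", "target", "strength", "tie"])

    def edges_vs_threshold(self, thetas: Sequence[float]) -> list[tuple[float, int]]:
        return edges_vs_threshold(self.candidates, thetas)

    def compare(self, other: "GeneInteractionResults") -> NetworkComparison:
        return compare_networks(self.network, other.network)

    def plot_edges_vs_threshold(self, thetas: Sequence[float], ax=None):
        """Line plot of accepted-edge count against theta."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        pts = self.edges_vs_threshold(thetas)
        ax.plot([t for t, _ in pts], [c for _, c in pts], marker="o")
        ax.set_xlabel(r"acceptance threshold $\theta$")
        ax.set_ylabel("accepted interactions")
        return ax

    def summary(self) -> str:
        """Human-readable account of the fit."""
        n_conv = sum(r.converged for r in self.pair_results)
        lines = [
            "Gene Interaction Model (paired RBM)",
            "=" * 48,
            f"genes:            {self.model.raw.n_genes}",
            f"samples:          {self.model.raw.n_samples}",
            f"pairs trained:    {len(self.pair_results)}",
            f"pairs converged:  {n_conv}",
            f"theta:            {self.theta}",
            f"accepted edges:   {len(self.network.edges)}",
            f"seed:             {self.seed}",
            "",
            f"{'regulator':<12}{'target':<12}{'strength':>10}{'tie':>6}",
            "-" * 48,
        ]
        for e in self.network.edges:
            lines.append(
                f"{e.regulator:<12}{e.target:<12}{e.strength:>10.4f}{str(e.tie):>6}"
            )
        if not self.network.edges:
            lines.append("(no accepted interactions at this theta)")
        return "\n".join(lines)
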