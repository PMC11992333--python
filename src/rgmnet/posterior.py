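"""Posterior summaries: reported graphs and network-motif probabilities.

The sampler returns posterior inclusion-probability matrices; this module
turns them into binary adjacency matrices, effect-weighted causal graphs,
and posterior probabilities of user-specified network motifs computed from
the retained gamma samples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "MotifSpec",
    "CausalGraph",
    "threshold_adjacency",
    "effective_effect_matrix",
    "build_graph",
    "network_motif_probability",
]


@dataclass(frozen=True)
class MotifSpec:
    """Binary adjacency sub-pattern among responses to score.

    ``Gamma[i, j] = 1`` requires the edge "response j -> response i" to be
    present (row = target, column = source, matching the model's A matrix).
    """

    Gamma: np.ndarray

    def __post_init__(self):
        G = np.asarray(self.Gamma)
        if G.ndim != 2 or G.shape[0] != G.shape[1]:
            raise ValueError("motif adjacency must be square")
        if not np.isin(G, (0, 1)).all():
            raise ValueError("motif adjacency must be binary")
        if np.diag(G).any():
            raise ValueError("motif adjacency must have a zero diagonal")
        object.__setattr__(self, "Gamma", G.astype(np.int8))

    @property
    def p(self) -> int:
        return self.Gamma.shape[0]


@dataclass(frozen=True)
class CausalGraph:
    """Reported causal network: one record per retained directed edge.

    Edges carry the posterior-mean effect (already masked by the 0.5
    inclusion threshold) and the posterior inclusion probability.
    Directions follow the structural matrix A: A[i, j] is the effect of
    response j on response i, stored as the edge j -> i.
    """

    p: int
    edges: list[tuple[int, int, float, float]]  # (source, target, effect, prob)

    def to_networkx(self):
        import networkx as nx

        G = nx.DiGraph()
        G.add_nodes_from(range(self.p))
        for src, tgt, eff, prob in self.edges:
            G.add_edge(src, tgt, effect=eff, inclusion_probability=prob)
        return G

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("source\ttarget\teffect\tinclusion_probability\n")
            for src, tgt, eff, prob in self.edges:
                fh.write(f"{src}\t{tgt}\t{eff!r}\t{prob!r}\n")

    def write_graphml(self, path) -> None:
        import networkx as nx

        nx.write_graphml(self.to_networkx(), path)


def threshold_adjacency(P: np.ndarray, zero_diagonal: bool = True) -> np.ndarray:
    """Binary adjacency from an inclusion-probability matrix.

    An edge is reported when its probability strictly exceeds 0.5; exactly
    0.5 stays out.  ``zero_diagonal`` forces the diagonal to 0 and is the
    default for response-response graphs (self-loops are excluded by the
    model); pass False for instrument-response matrices.
    """
    P = np.asarray(P, dtype=float)
    if np.isnan(P).any() or P.min(initial=0.0) < 0.0 or P.max(initial=0.0) > 1.0:
        raise ValueError("probabilities must lie in [0, 1]")
    out = (P > 0.5).astype(np.int8)
    if zero_diagonal and P.ndim == 2 and P.shape[0] == P.shape[1]:
        np.fill_diagonal(out, 0)
    return out


def effective_effect_matrix(AEst: np.ndarray, zAEst: np.ndarray) -> np.ndarray:
    """Posterior-mean effects masked by the reported adjacency: the
    elementwise product AEst * zAEst, zero wherever the edge is dropped."""
    AEst = np.asarray(AEst, dtype=float)
    zAEst = np.asarray(zAEst)
    if AEst.shape != zAEst.shape:
        raise ValueError("AEst and zAEst must have equal shapes")
    return AEst * zAEst


def build_graph(result) -> CausalGraph:
    """Assemble the reported causal network from a PosteriorResult."""
    eff = effective_effect_matrix(result.AEst, result.zAEst)
    prob = np.asarray(result.GammaEst, dtype=float)
    p = eff.shape[0]
    edges = [
        (int(j), int(i), float(eff[i, j]), float(prob[i, j]))
        for i in range(p)
        for j in range(p)
        if result.zAEst[i, j]
    ]
    return CausalGraph(p=p, edges=edges)


def network_motif_probability(
    motif: MotifSpec | np.ndarray, GammaPst: np.ndarray, mode: str = "containment"
) -> float:
    """Posterior probability of a network motif from retained gamma samples.

    ``containment`` (default) counts a sample as a hit when every edge of
    the motif is present, leaving the remaining cells unconstrained;
    ``exact`` requires the sample's adjacency to equal the motif exactly.
    """
    if not isinstance(motif, MotifSpec):
        motif = MotifSpec(motif)
    G = np.asarray(GammaPst)
    if G.ndim != 3 or G.shape[0] == 0:
        raise ValueError("GammaPst must be a nonempty stack of p x p samples")
    if G.shape[1:] != motif.Gamma.shape:
        raise ValueError(
            f"motif dimension {motif.Gamma.shape} does not match samples {G.shape[1:]}"
        )
    if mode == "containment":
        hits = (G[:, motif.Gamma == 1] == 1).all(axis=1)
    elif mode == "exact":
        hits = (G == motif.Gamma[None, :, :]).all(axis=(1, 2))
    else:
        raise ValueError("mode must be 'containment' or 'exact'")
    return float(hits.mean())
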