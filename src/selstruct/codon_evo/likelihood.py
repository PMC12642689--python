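"""Felsenstein-pruning likelihood for codon site-class mixtures.

The tree is flattened to arrays (postorder node list, parent pointers,
branch lengths); per-class transition matrices come from a symmetrized
eigendecomposition of the reversible rate matrix, so repeated likelihood
evaluations during optimization cost one eigendecomposition per site
class plus dense matrix products.  Gap codons are marginalized as missing
data.  Alignment columns are compressed to unique site patterns.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np

from selstruct._codes import get_code
from selstruct.codon_evo.model import SiteClassMixture, build_rate_matrix
from selstruct.seqdata import CodonAlignment, GAP_CODON

_LOG_FLOOR = 1e-300


class TreeError(ValueError):
    pass


@dataclass
class ArrayTree:
    """A rooted tree flattened for vectorized pruning.

    Leaves occupy node ids ``0..n_leaves-1`` in the order of ``taxa``;
    internal nodes follow; the root is the last postorder node.
    ``lengths[i]`` is the branch above node *i* (unused for the root).
    Under a reversible model the likelihood does not depend on root
    placement, so unrooted input trees are handled by treating the
    basal polytomy as the root.
    """

    taxa: list[str]
    parent: np.ndarray
    lengths: np.ndarray
    children: list[list[int]]
    postorder: list[int]

    @property
    def n_leaves(self) -> int:
        return len(self.taxa)

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def root(self) -> int:
        return self.postorder[-1]

    @property
    def n_branches(self) -> int:
        return self.n_nodes - 1

    def branch_vector(self) -> np.ndarray:
        """Branch lengths of all non-root nodes, in node-id order."""
        return np.array([self.lengths[i] for i in range(self.n_nodes) if i != self.root])

    def with_branch_vector(self, vec: np.ndarray) -> "ArrayTree":
        lengths = self.lengths.copy()
        ids = [i for i in range(self.n_nodes) if i != self.root]
        lengths[ids] = vec
        return ArrayTree(self.taxa, self.parent, lengths, self.children, self.postorder)

    # -- construction --------------------------------------------------
    @staticmethod
    def from_dendropy(tree: dendropy.Tree, taxa: list[str]) -> "ArrayTree":
        """Flatten a dendropy tree, matching leaves to alignment taxa."""
        tree = tree.clone(depth=1)
        tree.suppress_unifurcations()
        leaves = {lf.taxon.label.replace(" ", "_"): lf for lf in tree.leaf_node_iter()}
        missing = set(taxa) - set(leaves)
        extra = set(leaves) - set(taxa)
        if missing or extra:
            raise TreeError(
                f"tree/alignment taxa mismatch (missing {sorted(missing)}, "
                f"extra {sorted(extra)})"
            )
        ids: dict[int, int] = {}
        for i, name in enumerate(taxa):
            ids[id(leaves[name])] = i
        next_id = len(taxa)
        for node in tree.postorder_node_iter():
            if id(node) not in ids:
                ids[id(node)] = next_id
                next_id += 1
        n = next_id
        parent = np.full(n, -1, dtype=np.intp)
        lengths = np.zeros(n)
        children: list[list[int]] = [[] for _ in range(n)]
        postorder: list[int] = []
        for node in tree.postorder_node_iter():
            nid = ids[id(node)]
            postorder.append(nid)
            if node.parent_node is not None:
                parent[nid] = ids[id(node.parent_node)]
                children[parent[nid]].append(nid)
                lengths[nid] = node.edge.length if node.edge.length is not None else 0.0
        if np.any(lengths < 0):
            raise TreeError("negative branch length")
        return ArrayTree(list(taxa), parent, lengths, children, postorder)

    @staticmethod
    def from_newick(newick: str, taxa: list[str]) -> "ArrayTree":
        tree = dendropy.Tree.get(data=newick, schema="newick")
        return ArrayTree.from_dendropy(tree, taxa)

    @staticmethod
    def two_taxon(taxa: list[str], t: float) -> "ArrayTree":
        """Minimal tree for pairwise estimation: both leaves joined at a
        root, the full divergence ``t`` on one branch."""
        if len(taxa) != 2:
            raise TreeError("two_taxon tree needs exactly 2 taxa")
        parent = np.array([2, 2, -1], dtype=np.intp)
        lengths = np.array([t, 0.0, 0.0])
        return ArrayTree(list(taxa), parent, lengths, [[], [], [0, 1]], [0, 1, 2])


# ---------------------------------------------------------------------
# Pattern compression
# ---------------------------------------------------------------------

def encode_alignment(aln: CodonAlignment) -> np.ndarray:
    """Codon-index matrix (n_taxa, n_sites); gaps encode as -1."""
    code = get_code(aln.genetic_code)
    out = np.empty((aln.n_taxa, aln.site_count), dtype=np.intp)
    for i, seq in enumerate(aln.sequences):
        for col in range(aln.site_count):
            codon = seq[3 * col : 3 * col + 3]
            out[i, col] = -1 if codon == GAP_CODON else code.index[codon]
    return out


def compress_patterns(codes: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Unique site patterns, their weights, and a site->pattern map."""
    patterns, inverse, counts = np.unique(
        codes.T, axis=0, return_inverse=True, return_counts=True
    )
    return patterns.T, counts.astype(float), inverse


# ---------------------------------------------------------------------
# Transition matrices via symmetrized eigendecomposition
# ---------------------------------------------------------------------

def eigen_reversible(Q: np.ndarray, pi: np.ndarray):
    """Eigendecompose a reversible rate matrix.

    Returns (lam, right, left) with exp(Q t) = right @ diag(exp(lam t)) @ left.
    """
    d = np.sqrt(pi)
    S = Q * (d[:, None] / d[None, :])
    S = 0.5 * (S + S.T)
    lam, V = np.linalg.eigh(S)
    right = V / d[:, None]
    left = V.T * d[None, :]
    return lam, right, left


@dataclass
class MixtureEngine:
    """Per-class eigendecompositions for one (mixture, kappa, pi) setting.

    Class matrices share a single scale factor — the mixture-average
    substitution rate — so a branch length is the expected number of
    substitutions per codon averaged over site classes, and sites in
    high-omega classes substitute faster than the average.  This is the
    standard convention for codon site models and what gives per-site
    positive selection most of its signal.
    """

    mixture: SiteClassMixture
    kappa: float
    pi: np.ndarray
    genetic_code: int = 1
    lam: np.ndarray = field(init=False)
    right: np.ndarray = field(init=False)
    left: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        K = self.mixture.n_classes
        n = len(self.pi)
        self.lam = np.empty((K, n))
        self.right = np.empty((K, n, n))
        self.left = np.empty((K, n, n))
        Qs = np.empty((K, n, n))
        rates = np.empty(K)
        for k, omega in enumerate(self.mixture.class_omegas):
            model = build_rate_matrix(
                self.kappa, float(omega), self.pi, self.genetic_code,
                normalize=False,
            )
            Qs[k] = model.Q
            rates[k] = -(self.pi * np.diag(model.Q)).sum()
        scale = float(self.mixture.class_weights @ rates)
        if scale <= 0:
            raise ValueError("degenerate mixture (zero average rate)")
        for k in range(K):
            self.lam[k], self.right[k], self.left[k] = eigen_reversible(
                Qs[k] / scale, self.pi
            )

    def transition_matrices(self, t: float) -> np.ndarray:
        """(K, n, n) stack of exp(Q_k t); rows clipped to be proper."""
        P = (self.right * np.exp(self.lam * t)[:, None, :]) @ self.left
        np.maximum(P, 0.0, out=P)
        return P


def site_class_likelihoods(
    patterns: np.ndarray,
    tree: ArrayTree,
    engine: MixtureEngine,
) -> np.ndarray:
    """Per-class, per-pattern likelihoods L_k(pattern), shape (K, n_patterns).

    Standard pruning: each node passes its parent the message
    ``P(t_child) @ partial_child``; leaf partials are indicators (all ones
    for a gap, i.e. missing data).
    """
    K = engine.mixture.n_classes
    npat = patterns.shape[1]
    n_states = len(engine.pi)
    partial: list[np.ndarray | None] = [None] * tree.n_nodes
    for node in tree.postorder:
        kids = tree.children[node]
        if not kids:
            continue
        acc = np.ones((K, npat, n_states))
        for child in kids:
            P = engine.transition_matrices(tree.lengths[child])
            if child < tree.n_leaves:
                obs = patterns[child]
                gap = obs < 0
                # message[k, p, i] = P[k, i, obs_p]; 1 for gaps
                msg = P[:, :, np.where(gap, 0, obs)].transpose(0, 2, 1)
                if gap.any():
                    msg[:, gap, :] = 1.0
            else:
                msg = partial[child] @ P.transpose(0, 2, 1)
            acc *= msg
        partial[node] = acc
    root = partial[tree.root]
    if root is None:  # single-leaf degenerate tree
        obs = patterns[0]
        root = np.ones((K, npat, n_states))
        mask = obs >= 0
        root[:, mask, :] = 0.0
        root[:, np.where(mask)[0], obs[mask]] = 1.0
    return root @ engine.pi


def log_likelihood(
    aln: CodonAlignment,
    tree: ArrayTree,
    mixture: SiteClassMixture,
    kappa: float,
    pi: np.ndarray,
) -> tuple[float, np.ndarray]:
    """Mixture log-likelihood and per-site class likelihoods.

    Returns ``(ell, site_class_lik)`` where ``site_class_lik`` has shape
    (n_classes, n_sites) expanded back from the compressed patterns;
    ``ell = sum_sites log sum_k w_k L_k(site)``.
    """
    codes = encode_alignment(aln)
    patterns, weights, inverse = compress_patterns(codes)
    engine = MixtureEngine(mixture, kappa, pi, aln.genetic_code)
    f = site_class_likelihoods(patterns, tree, engine)
    mix = mixture.class_weights @ f
    if np.any(~np.isfinite(mix)):
        bad = int(np.where(~np.isfinite(mix))[0][0])
        raise FloatingPointError(f"non-finite site likelihood at pattern {bad}")
    ell = float(weights @ np.log(np.maximum(mix, _LOG_FLOOR)))
    return ell, f[:, inverse]
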