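"""Phylogenetic comparative analysis: Blomberg's K and BM ancestral states.

Under Brownian motion (BM) on a rooted tree with branch lengths, tip values
are multivariate normal with covariance sigma^2 * C, where C[i, j] is the
shared root-to-MRCA path length of tips i and j (the phylogenetic
variance-covariance matrix). Blomberg's K compares the observed ratio of
among-tip variance to phylogenetically corrected variance against its BM
expectation; K ~ 1 under BM, K -> 0 when trait values ignore the phylogeny,
K > 1 when relatives are even more similar than BM predicts. Significance
comes from a randomization test shuffling trait values across tips.

Ancestral character estimation under BM uses the GLS / ML estimator: the
root state is the phylogenetically weighted mean, each internal node's
state is the conditional expectation of the node given the tips at the ML
root state, and states are interpolated linearly along edges for mapping.

Newick I/O and pruning are delegated to dendropy; all statistics are
computed here from the C matrix by dense linear algebra.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve

__all__ = [
    "parse_newick",
    "write_newick",
    "prune_to_taxa",
    "phylo_vcv",
    "blomberg_k",
    "blomberg_k_test",
    "KResult",
    "ancestral_states_ml",
    "AncestralMap",
    "load_default_tree",
    "random_tree",
]


def random_tree(
    n_tips: int,
    seed: int | None = 0,
    min_bl: float = 0.1,
    max_bl: float = 2.0,
    prefix: str = "T",
) -> "dendropy.Tree":
    """Random rooted binary tree with uniform branch lengths (for testing)."""
    if n_tips < 2:
        raise ValueError("need at least 2 tips")
    rng = np.random.default_rng(seed)
    nodes = [f"{prefix}{i}:{rng.uniform(min_bl, max_bl):.6f}" for i in range(n_tips)]
    while len(nodes) > 2:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        nodes.append(f"({a},{b}):{rng.uniform(min_bl, max_bl):.6f}")
    return parse_newick(f"({nodes[0]},{nodes[1]});")


def parse_newick(text: str, default_edge_length: float | None = None) -> dendropy.Tree:
    """Parse a rooted Newick tree with branch lengths.

    Missing edge lengths raise unless ``default_edge_length`` is given;
    duplicate tip labels raise. Zero-length branches are replaced by
    1e-8 x tree depth (with a warning) so the BM covariance stays
    invertible.
    """
    try:
        tree = dendropy.Tree.get(
            data=text, schema="newick", suppress_internal_node_taxa=True
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise ValueError(f"malformed Newick: {exc}") from exc
    labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
    if len(labels) != len(set(labels)):
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        raise ValueError(f"duplicate tip labels: {dupes}")
    if len(labels) < 2:
        raise ValueError("tree must have at least 2 tips")
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            continue
        if edge.length is None:
            if default_edge_length is None:
                raise ValueError("tree has edges without branch lengths")
            edge.length = default_edge_length
        if edge.length < 0:
            raise ValueError("negative branch length")
    depth = max(lf.distance_from_root() for lf in tree.leaf_node_iter())
    eps = 1e-8 * (depth if depth > 0 else 1.0)
    n_zero = 0
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            continue
        if edge.length == 0:
            edge.length = eps
            n_zero += 1
    if n_zero:
        warnings.warn(f"replaced {n_zero} zero-length branches by {eps:g}")
    return tree


def write_newick(tree: dendropy.Tree) -> str:
    return tree.as_string(schema="newick", suppress_rooting=True).strip()


def prune_to_taxa(tree: dendropy.Tree, taxa: list[str]) -> dendropy.Tree:
    """Induced subtree on ``taxa``; unifurcations suppressed, lengths summed."""
    tips = {lf.taxon.label for lf in tree.leaf_node_iter()}
    missing = sorted(set(taxa) - tips)
    if missing:
        raise ValueError(f"taxa not in tree: {missing}")
    pruned = tree.extract_tree_with_taxa_labels(labels=set(taxa))
    # extract_tree keeps a root edge remnant; drop any root edge length so
    # depths are measured from the retained MRCA structure consistently
    return pruned


def _node_label(node: dendropy.Node, k: int) -> str:
    if node.taxon is not None:
        return node.taxon.label
    if node.label:
        return node.label
    return f"node{k}"


def phylo_vcv(tree: dendropy.Tree) -> pd.DataFrame:
    """Phylogenetic variance-covariance matrix C of the tips.

    C[i, j] = path length from the root to the MRCA of tips i and j;
    the diagonal holds root-to-tip depths.
    """
    tips = list(tree.leaf_node_iter())
    labels = [lf.taxon.label for lf in tips]
    n = len(tips)
    # leaf membership sets per node, accumulated postorder
    leaf_idx = {id(lf): i for i, lf in enumerate(tips)}
    C = np.zeros((n, n))
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            node._leafset = frozenset([leaf_idx[id(node)]])
        else:
            node._leafset = frozenset().union(*(c._leafset for c in node.child_nodes()))
    depth = {id(tree.seed_node): 0.0}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        depth[id(node)] = depth[id(node.parent_node)] + (node.edge.length or 0.0)
    for node in tree.preorder_node_iter():
        d = depth[id(node)]
        children = node.child_nodes()
        if node.is_leaf():
            i = leaf_idx[id(node)]
            C[i, i] = d
            continue
        # pairs of tips whose MRCA is exactly this node: tips in different children
        for a in range(len(children)):
            for b in range(a + 1, len(children)):
                ia = sorted(children[a]._leafset)
                ib = sorted(children[b]._leafset)
                C[np.ix_(ia, ib)] = d
                C[np.ix_(ib, ia)] = d
    for node in tree.postorder_node_iter():
        del node._leafset
    df = pd.DataFrame(C, index=labels, columns=labels)
    if np.any(np.diag(C) <= 0):
        raise ValueError("tree has tips at zero depth; branch lengths required")
    return df


def _align_traits(C: pd.DataFrame, traits: pd.Series) -> np.ndarray:
    traits = pd.Series(traits)
    traits.index = [str(ix).strip() for ix in traits.index]
    missing = [l for l in C.index if l not in traits.index]
    extra = [l for l in traits.index if l not in C.index]
    if missing or extra:
        raise ValueError(f"trait/tip mismatch: missing={missing}, extra={extra}")
    x = traits.loc[list(C.index)].to_numpy(float)
    if not np.all(np.isfinite(x)):
        raise ValueError("trait values must be finite")
    return x


def _k_statistic_many(C: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Blomberg's K for each row of X (replicates x tips), one factorization.

    K = (MSE0/MSE) / E[MSE0/MSE] with the GLS mean a = (1'C^-1 x)/(1'C^-1 1),
    MSE0 = (x-a)'(x-a)/(n-1), MSE = (x-a)'C^-1(x-a)/(n-1) and
    E[MSE0/MSE] = (tr C - n/(1'C^-1 1)) / (n-1).
    """
    n = C.shape[0]
    cf = cho_factor(C)
    one = np.ones(n)
    Cinv1 = cho_solve(cf, one)
    denom1 = float(one @ Cinv1)
    a = (X @ Cinv1) / denom1
    R = X - a[:, None]
    mse0 = np.einsum("ij,ij->i", R, R)
    CinvR = cho_solve(cf, R.T).T
    mse = np.einsum("ij,ij->i", R, CinvR)
    expected = (np.trace(C) - n / denom1) / (n - 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        return (mse0 / mse) / expected


def blomberg_k(tree_or_C, traits: pd.Series) -> float:
    """Blomberg's K phylogenetic signal statistic for one trait.

    Accepts a tree or a precomputed C DataFrame. Requires >= 3 tips and a
    non-constant trait.
    """
    C = tree_or_C if isinstance(tree_or_C, pd.DataFrame) else phylo_vcv(tree_or_C)
    x = _align_traits(C, traits)
    if len(x) < 3:
        raise ValueError("need at least 3 tips")
    if np.ptp(x) == 0:
        raise ValueError("constant trait: K undefined")
    return float(_k_statistic_many(C.to_numpy(), x[None, :])[0])


@dataclass(frozen=True)
class KResult:
    K: float
    p: float
    n_perm: int
    seed: int | None


def blomberg_k_test(
    tree_or_C, traits: pd.Series, n_perm: int = 1000, seed: int | None = 0
) -> KResult:
    """Randomization test for K: shuffle trait values across tips.

    p = (1 + #{K_perm >= K_obs}) / (n_perm + 1), the add-one estimator.
    """
    if n_perm < 99:
        raise ValueError("need n_perm >= 99")
    C = tree_or_C if isinstance(tree_or_C, pd.DataFrame) else phylo_vcv(tree_or_C)
    x = _align_traits(C, traits)
    if len(x) < 3:
        raise ValueError("need at least 3 tips")
    if np.ptp(x) == 0:
        raise ValueError("constant trait: K undefined")
    Cn = C.to_numpy()
    k_obs = float(_k_statistic_many(Cn, x[None, :])[0])
    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(x) for _ in range(n_perm)])
    k_perm = _k_statistic_many(Cn, perms)
    p = (1.0 + np.sum(k_perm >= k_obs)) / (n_perm + 1.0)
    return KResult(K=k_obs, p=float(p), n_perm=n_perm, seed=seed)


@dataclass
class AncestralMap:
    """ML node states plus along-edge linear interpolation."""

    node_states: pd.Series  # node label -> state (tips included)
    edge_grid: pd.DataFrame  # columns: parent, child, position (0..1), state
    tree_newick: str


def ancestral_states_ml(
    tree: dendropy.Tree, traits: pd.Series, grid: int = 10
) -> AncestralMap:
    """BM maximum-likelihood (GLS) ancestral states with edge interpolation.

    Each internal node's state is mu + s' C^-1 (x - mu), where mu is the
    GLS root estimate and s[j] is the shared path length between the node
    and tip j (equivalently, the phylogenetically weighted mean after
    re-rooting at that node). Edge states are linear between endpoint
    states at ``grid`` points per edge.
    """
    if grid < 1:
        raise ValueError("grid must be >= 1")
    C = phylo_vcv(tree)
    x = _align_traits(C, traits)
    if np.ptp(x) == 0:
        # BM likelihood degenerates; every node equals the common value
        pass
    n = len(x)
    cf = cho_factor(C.to_numpy())
    one = np.ones(n)
    Cinv1 = cho_solve(cf, one)
    mu = float(x @ Cinv1 / (one @ Cinv1))
    w = cho_solve(cf, x - mu * one)

    tip_order = {lbl: i for i, lbl in enumerate(C.index)}
    depth = {id(tree.seed_node): 0.0}
    for node in tree.preorder_node_iter():
        if node is not tree.seed_node:
            depth[id(node)] = depth[id(node.parent_node)] + (node.edge.length or 0.0)
    # leaf index sets per node
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            node._leaves = frozenset([tip_order[node.taxon.label]])
        else:
            node._leaves = frozenset().union(*(c._leaves for c in node.child_nodes()))

    states: dict[str, float] = {}
    labels: dict[int, str] = {}
    k = 0
    for node in tree.preorder_node_iter():
        lbl = _node_label(node, k)
        labels[id(node)] = lbl
        k += 1
        if node.is_leaf():
            states[lbl] = float(x[tip_order[node.taxon.label]])
            continue
        # shared path length between this node and each tip: depth of the
        # MRCA, which is this node for its descendants and the nearest
        # common ancestor for the rest
        s = np.zeros(n)
        s[list(node._leaves)] = depth[id(node)]
        anc = node
        while anc.parent_node is not None:
            parent = anc.parent_node
            newly = parent._leaves - anc._leaves
            s[list(newly)] = depth[id(parent)]
            anc = parent
        states[lbl] = mu + float(s @ w)

    rows = []
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        p_lbl = labels[id(node.parent_node)]
        c_lbl = labels[id(node)]
        sp, sc = states[p_lbl], states[c_lbl]
        for g in range(grid + 1):
            frac = g / grid
            rows.append(
                {"parent": p_lbl, "child": c_lbl, "position": frac,
                 "state": sp + (sc - sp) * frac}
            )
    for node in tree.postorder_node_iter():
        del node._leaves
    return AncestralMap(
        node_states=pd.Series(states, name="state"),
        edge_grid=pd.DataFrame(rows),
        tree_newick=write_newick(tree),
    )


def load_default_tree() -> dendropy.Tree:
    """The packaged 17-taxon scyphozoan example tree.

    Topology follows the major-lineage structure of the class (Coronatae
    sister to Discomedusae; "Semaeostomeae" families paraphyletic with
    respect to a monophyletic Rhizostomeae) but the branch lengths are
    synthetic: this is a stand-in fixture for testing and examples, not an
    inferred phylogeny.
    """
    from importlib.resources import files

    text = (files("pulsekin") / "data" / "scyphozoa17_synthetic.nwk").read_text()
    return parse_newick(text)
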