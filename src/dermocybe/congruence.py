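"""Chemo-phylogenetic congruence machinery.

The congruence analysis asks whether species with similar pigment chemistry
are also close in their rDNA ITS sequences.  Both data types are reduced to
Bray-Curtis distance matrices over the same taxa - pigment profiles directly
from their relative-quantity vectors, alignments through a per-column
five-state (A, C, G, T, gap) one-hot encoding, which makes the sequence
matrix commensurable with the pigment matrix under the same dissimilarity
(and is provably equal to the p-distance with gaps as a fifth state).
Hierarchical dendrograms use the Ward.D variant: the Lance-Williams update
with Ward coefficients applied to the input dissimilarities as given, without
squaring.  Agreement is quantified by a tanglegram entanglement score and a
one-sided Mantel permutation test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

_STATE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3, "-": 4, "N": 5}
_N_CODE = 5


@dataclass
class DistanceMatrix:
    """Labelled symmetric dissimilarity matrix with zero diagonal."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.labels = list(self.labels)
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if len(set(self.labels)) != n:
            raise ValueError("duplicate taxon labels")
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match label count")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(self.values), 0.0, atol=1e-10):
            raise ValueError("distance matrix diagonal is not zero")
        if (self.values < -1e-12).any():
            raise ValueError("distances must be non-negative")

    @property
    def n(self) -> int:
        return len(self.labels)

    def reordered(self, labels: list[str]) -> "DistanceMatrix":
        """Return the same matrix with rows/columns in the given label order."""
        if set(labels) != set(self.labels):
            raise ValueError("label sets differ")
        idx = [self.labels.index(l) for l in labels]
        return DistanceMatrix(labels, self.values[np.ix_(idx, idx)])

    def lower_triangle(self) -> np.ndarray:
        i, j = np.tril_indices(self.n, k=-1)
        return self.values[i, j]


@dataclass
class AlignedSequenceSet:
    """A multiple sequence alignment over {A, C, G, T, -, N}."""

    names: list[str]
    sequences: list[str]

    def __post_init__(self) -> None:
        if len(self.names) != len(self.sequences):
            raise ValueError("names and sequences differ in number")
        if len(set(self.names)) != len(self.names):
            raise ValueError("duplicate sequence names")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) > 1:
            raise ValueError("alignment sequences differ in length")
        self.sequences = [s.upper() for s in self.sequences]
        for name, seq in zip(self.names, self.sequences):
            bad = set(seq) - set(_STATE_INDEX)
            if bad:
                raise ValueError(f"sequence {name!r} contains invalid symbols {bad}")

    @property
    def n_taxa(self) -> int:
        return len(self.names)

    @property
    def length(self) -> int:
        return len(self.sequences[0]) if self.sequences else 0

    def encoded(self) -> np.ndarray:
        """Integer-coded alignment (taxa x columns), N coded separately."""
        return np.array(
            [[_STATE_INDEX[ch] for ch in seq] for seq in self.sequences], dtype=np.int8
        )


@dataclass
class Dendrogram:
    """Binary agglomerative merge tree.

    ``merges`` follows the usual linkage convention: row k merges cluster ids
    ``left``/``right`` (ids 0..n-1 are leaves in ``labels`` order, id n+k is
    the cluster created by row k) at ``height``.
    """

    labels: list[str]
    merges: list[tuple[int, int, float]]

    def __post_init__(self) -> None:
        n = len(self.labels)
        if len(self.merges) != n - 1:
            raise ValueError("a binary dendrogram over n leaves needs n-1 merges")

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    def heights(self) -> list[float]:
        return [h for _, _, h in self.merges]

    def _children(self) -> dict[int, tuple[int, int]]:
        n = self.n_leaves
        return {n + k: (a, b) for k, (a, b, _) in enumerate(self.merges)}

    def leaf_sets(self) -> dict[int, frozenset[int]]:
        """Leaf-index set under every node id."""
        n = self.n_leaves
        sets: dict[int, frozenset[int]] = {i: frozenset([i]) for i in range(n)}
        for k, (a, b, _) in enumerate(self.merges):
            sets[n + k] = sets[a] | sets[b]
        return sets

    def cophenetic(self) -> DistanceMatrix:
        """Pairwise merge heights at the lowest common ancestor."""
        n = self.n_leaves
        d = np.zeros((n, n))
        sets = self.leaf_sets()
        for k, (a, b, h) in enumerate(self.merges):
            left, right = sets[a], sets[b]
            for i in left:
                for j in right:
                    d[i, j] = d[j, i] = h
        return DistanceMatrix(self.labels, d)

    def leaf_order(self) -> list[str]:
        """Canonical left-to-right leaf order.

        At every internal node the child whose subtree contains the smaller
        minimum leaf index is placed first, which makes the ordering (and
        everything derived from it) deterministic.
        """
        n = self.n_leaves
        children = self._children()
        sets = self.leaf_sets()

        def walk(node: int) -> list[int]:
            if node < n:
                return [node]
            a, b = children[node]
            first, second = (a, b) if min(sets[a]) <= min(sets[b]) else (b, a)
            return walk(first) + walk(second)

        root = n + len(self.merges) - 1
        return [self.labels[i] for i in walk(root)]


def bray_curtis_matrix(abundance, labels: list[str] | None = None) -> DistanceMatrix:
    """Pairwise Bray-Curtis distance matrix of a taxa x features table.

    BC(x, y) = 1 - 2 Σ min(x_i, y_i) / Σ (x_i + y_i).  Accepts a pandas
    DataFrame (index = taxa) or an array plus explicit labels.  Negative
    entries and all-zero rows are rejected.
    """
    if hasattr(abundance, "values") and hasattr(abundance, "index"):
        labels = [str(x) for x in abundance.index]
        x = np.asarray(abundance.values, dtype=float)
    else:
        x = np.asarray(abundance, dtype=float)
        if labels is None:
            raise ValueError("labels required when passing a bare array")
    if (x < 0).any():
        raise ValueError("abundance entries must be non-negative")
    row_sums = x.sum(axis=1)
    if (row_sums == 0).any():
        bad = labels[int(np.flatnonzero(row_sums == 0)[0])]
        raise ValueError(f"all-zero abundance row for taxon {bad!r}")
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        shared = np.minimum(x[i], x[i + 1 :]).sum(axis=1)
        d[i, i + 1 :] = 1.0 - 2.0 * shared / (row_sums[i] + row_sums[i + 1 :])
    d = d + d.T
    return DistanceMatrix(list(labels), d)


def alignment_distance(a: AlignedSequenceSet) -> DistanceMatrix:
    """Bray-Curtis distance between one-hot encoded aligned sequences.

    Each column is encoded over the five states A, C, G, T and gap; N
    contributes to no state and any column in which either member of a pair
    carries N is excluded for that pair.  On N-free data this equals the
    p-distance with gap treated as a fifth character state.
    """
    if a.n_taxa < 2:
        raise ValueError("need at least two sequences")
    codes = a.encoded()
    n = a.n_taxa
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            xi, xj = codes[i], codes[j]
            mask = (xi != _N_CODE) & (xj != _N_CODE)
            m = int(mask.sum())
            if m == 0:
                raise ValueError(
                    f"no comparable columns between {a.names[i]!r} and {a.names[j]!r}"
                )
            # one-hot encode the comparable columns over the 5 states
            onehot_i = np.zeros((m, 5))
            onehot_j = np.zeros((m, 5))
            onehot_i[np.arange(m), xi[mask]] = 1.0
            onehot_j[np.arange(m), xj[mask]] = 1.0
            shared = np.minimum(onehot_i, onehot_j).sum()
            d[i, j] = d[j, i] = 1.0 - 2.0 * shared / (2.0 * m)
    return DistanceMatrix(list(a.names), d)


def ward_cluster(d: DistanceMatrix, variant: str = "ward.D") -> Dendrogram:
    """Agglomerative clustering with the Ward Lance-Williams update.

    ``ward.D`` applies the update to the dissimilarities as given (matching
    the classic hclust behaviour of that name); ``ward.D2`` squares the input
    first and reports square-rooted heights.  Ties are broken
    deterministically: among equally close pairs, the pair whose clusters
    contain the lowest original leaf indices merges first.
    """
    if variant not in ("ward.D", "ward.D2"):
        raise ValueError("variant must be 'ward.D' or 'ward.D2'")
    n = d.n
    if n < 2:
        raise ValueError("need at least two taxa to cluster")
    work = d.values.copy()
    if variant == "ward.D2":
        work = work**2
    # active cluster bookkeeping: id -> (size, min original leaf index)
    size = {i: 1 for i in range(n)}
    min_leaf = {i: i for i in range(n)}
    dist: dict[tuple[int, int], float] = {}
    for i in range(n):
        for j in range(i + 1, n):
            dist[(i, j)] = float(work[i, j])
    active = list(range(n))
    merges: list[tuple[int, int, float]] = []
    next_id = n
    while len(active) > 1:
        best = None
        for ai in range(len(active)):
            for aj in range(ai + 1, len(active)):
                a, b = active[ai], active[aj]
                key = (min(a, b), max(a, b))
                dv = dist[key]
                rank = (dv, min(min_leaf[a], min_leaf[b]), max(min_leaf[a], min_leaf[b]))
                if best is None or rank < best[0]:
                    best = (rank, a, b)
        _, a, b = best
        h = dist[(min(a, b), max(a, b))]
        new = next_id
        next_id += 1
        for k in active:
            if k in (a, b):
                continue
            dka = dist[(min(k, a), max(k, a))]
            dkb = dist[(min(k, b), max(k, b))]
            dab = dist[(min(a, b), max(a, b))]
            na, nb, nk = size[a], size[b], size[k]
            dnew = ((na + nk) * dka + (nb + nk) * dkb - nk * dab) / (na + nb + nk)
            dist[(min(k, new), max(k, new))] = dnew
        size[new] = size[a] + size[b]
        min_leaf[new] = min(min_leaf[a], min_leaf[b])
        active = [k for k in active if k not in (a, b)] + [new]
        merges.append((a, b, float(h)))
    if variant == "ward.D2":
        merges = [(a, b, float(np.sqrt(h))) for a, b, h in merges]
    return Dendrogram(list(d.labels), merges)


def cophenetic(t: Dendrogram) -> DistanceMatrix:
    """Cophenetic distance matrix (LCA merge heights) of a dendrogram."""
    return t.cophenetic()


@dataclass
class MantelResult:
    r: float
    p: float
    permutations: int
    seed: int


def mantel(
    d1: DistanceMatrix,
    d2: DistanceMatrix,
    permutations: int = 999,
    seed: int = 0,
) -> MantelResult:
    """One-sided Mantel permutation test of matrix correlation.

    The statistic is the Pearson correlation of the strictly-lower-triangle
    entries after aligning ``d2`` to ``d1``'s label order.  The null
    distribution is generated by simultaneous row/column permutation of the
    second matrix; p = (1 + #{r_perm >= r_obs}) / (permutations + 1), so the
    attainable p resolution is exactly 1/(permutations + 1).
    """
    if set(d1.labels) != set(d2.labels):
        raise ValueError("distance matrices cover different taxa")
    d2 = d2.reordered(d1.labels)
    x = d1.lower_triangle()
    if np.ptp(x) == 0 or np.ptp(d2.lower_triangle()) == 0:
        raise ValueError("constant distance triangle; Mantel r undefined")
    n = d1.n
    il, jl = np.tril_indices(n, k=-1)
    xc = x - x.mean()
    xnorm = np.sqrt((xc**2).sum())

    def corr(mat: np.ndarray) -> float:
        y = mat[il, jl]
        yc = y - y.mean()
        return float((xc * yc).sum() / (xnorm * np.sqrt((yc**2).sum())))

    r_obs = corr(d2.values)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(permutations):
        perm = rng.permutation(n)
        if corr(d2.values[np.ix_(perm, perm)]) >= r_obs - 1e-12:
            count += 1
    p = (1 + count) / (permutations + 1)
    return MantelResult(r=r_obs, p=float(p), permutations=permutations, seed=seed)


def entanglement_from_orders(left_order: list[str], right_order: list[str]) -> float:
    """Entanglement of two leaf orderings over the same labels, in [0, 1].

    With positions u_i and v_i of each label in the two orders, the score is
    Σ (u_i - v_i)² normalised by its value under exact reversal: 0 for
    identical orders, 1 for one order being the reverse of the other.
    """
    if set(left_order) != set(right_order):
        raise ValueError("leaf orders cover different labels")
    n = len(left_order)
    if n < 2:
        return 0.0
    pos_r = {lab: i for i, lab in enumerate(right_order)}
    u = np.arange(n)
    v = np.array([pos_r[lab] for lab in left_order])
    num = float(((u - v) ** 2).sum())
    denom = float(((u - u[::-1]) ** 2).sum())
    return num / denom


def entanglement(left: Dendrogram, right: Dendrogram) -> float:
    """Entanglement of two dendrograms' canonical leaf orders."""
    if set(left.labels) != set(right.labels):
        raise ValueError("dendrograms cover different leaf sets")
    return entanglement_from_orders(left.leaf_order(), right.leaf_order())


@dataclass
class TanglegramResult:
    """Bundled output of the full congruence analysis."""

    pigment_distances: DistanceMatrix
    sequence_distances: DistanceMatrix
    pigment_dendrogram: Dendrogram
    sequence_dendrogram: Dendrogram
    entanglement: float
    mantel: MantelResult
    ward_variant: str = "ward.D"

    @property
    def taxa(self) -> list[str]:
        return list(self.pigment_distances.labels)


def tanglegram_report(
    profiles,
    alignment: AlignedSequenceSet,
    permutations: int = 999,
    seed: int = 0,
    ward_variant: str = "ward.D",
) -> TanglegramResult:
    """Run the full congruence pipeline on a pigment matrix and an alignment.

    ``profiles`` is a taxa x pigments abundance table (DataFrame).  Both data
    sets must cover the same taxa.  Computes both Bray-Curtis matrices, Ward
    dendrograms, the entanglement of their leaf orders, and the Mantel test.
    """
    d_pig = bray_curtis_matrix(profiles)
    d_seq = alignment_distance(alignment)
    if set(d_pig.labels) != set(d_seq.labels):
        raise ValueError("profile taxa and alignment taxa differ")
    d_seq = d_seq.reordered(d_pig.labels)
    t_pig = ward_cluster(d_pig, ward_variant)
    t_seq = ward_cluster(d_seq, ward_variant)
    return TanglegramResult(
        pigment_distances=d_pig,
        sequence_distances=d_seq,
        pigment_dendrogram=t_pig,
        sequence_dendrogram=t_seq,
        entanglement=entanglement(t_pig, t_seq),
        mantel=mantel(d_pig, d_seq, permutations=permutations, seed=seed),
        ward_variant=ward_variant,
    )
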