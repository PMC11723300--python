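"""Pairwise genetic distances: p-distance and Kimura 2-parameter (K2P).

Sites where either sequence carries a gap or an ambiguity code are excluded
pair by pair (pairwise deletion). Transitions are A<->G and C<->T; every
other mismatch is a transversion. The K2P distance is

    d = -1/2 * ln((1 - 2P - Q) * sqrt(1 - 2Q))

with P and Q the transition and transversion proportions over comparable
sites. Pairs for which the logarithm's argument is non-positive (saturated
pairs) are flagged inapplicable (NaN) rather than raising.

A site (column) bootstrap provides standard errors for every pairwise
distance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from barcodekit.seqio import MarkerDataset

_TRANSITION_PAIRS = {frozenset("AG"), frozenset("CT")}

# uint8 encoding: A=0 C=1 G=2 T=3, anything else (gap/ambiguity) = 255
_ENCODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i

#: purine/pyrimidine class of the encoded base (A,G -> 0; C,T -> 1)
_PURINE = np.array([0, 1, 0, 1], dtype=np.uint8)


@dataclass(frozen=True)
class PairCounts:
    """Transition/transversion tally for one aligned sequence pair."""

    P: float  # transition proportion
    Q: float  # transversion proportion
    n: int  # comparable sites

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("PairCounts requires n >= 1")
        if not (0.0 <= self.P + self.Q <= 1.0 + 1e-12):
            raise ValueError("P + Q must lie in [0, 1]")

    @property
    def p(self) -> float:
        """Plain proportion of differing sites (p-distance)."""
        return self.P + self.Q


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distance matrix keyed by sample id.

    ``values`` is square with a zero diagonal; saturated K2P cells are NaN.
    ``comparable_sites[i, j]`` counts the sites both sequences could be
    compared at.
    """

    ids: list[str]
    model: str
    values: np.ndarray
    comparable_sites: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match ids")
        if not np.allclose(np.nan_to_num(self.values), np.nan_to_num(self.values.T)):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.values), 0.0):
            raise ValueError("diagonal must be zero")

    def __len__(self) -> int:
        return len(self.ids)

    def get(self, a: str, b: str) -> float:
        i, j = self.ids.index(a), self.ids.index(b)
        return float(self.values[i, j])

    def n_inapplicable(self) -> int:
        iu = np.triu_indices(len(self.ids), k=1)
        return int(np.isnan(self.values[iu]).sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)

    def to_long(self) -> pd.DataFrame:
        rows = []
        for i in range(len(self.ids)):
            for j in range(i + 1, len(self.ids)):
                rows.append(
                    {
                        "id_a": self.ids[i],
                        "id_b": self.ids[j],
                        "model": self.model,
                        "distance": self.values[i, j],
                        "n_sites": int(self.comparable_sites[i, j]),
                    }
                )
        return pd.DataFrame(rows)


def _encode(seq: str) -> np.ndarray:
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def pair_counts(seq_a: str, seq_b: str) -> PairCounts:
    """Tally transitions and transversions between two aligned sequences."""
    if len(seq_a) != len(seq_b):
        raise ValueError("sequences must be aligned to equal length")
    a, b = _encode(seq_a), _encode(seq_b)
    ok = (a != 255) & (b != 255)
    n = int(ok.sum())
    if n == 0:
        raise ValueError("no comparable sites between the two sequences")
    a, b = a[ok], b[ok]
    diff = a != b
    transitions = int((diff & (_PURINE[a] == _PURINE[b])).sum())
    transversions = int(diff.sum()) - transitions
    return PairCounts(P=transitions / n, Q=transversions / n, n=n)


def p_distance(seq_a: str, seq_b: str) -> float | None:
    """Proportion of differing comparable sites; None if none comparable."""
    try:
        c = pair_counts(seq_a, seq_b)
    except ValueError:
        return None
    return c.p


def k2p_distance(counts: PairCounts) -> float:
    """Kimura 2-parameter distance; NaN when the pair is saturated."""
    w1 = 1.0 - 2.0 * counts.P - counts.Q
    w2 = 1.0 - 2.0 * counts.Q
    if w1 <= 0.0 or w2 <= 0.0:
        return float("nan")
    return -0.5 * np.log(w1 * np.sqrt(w2))


def _pair_distance(a: np.ndarray, b: np.ndarray, model: str) -> tuple[float, int]:
    ok = (a != 255) & (b != 255)
    n = int(ok.sum())
    if n == 0:
        raise ValueError("pair with zero comparable sites")
    aa, bb = a[ok], b[ok]
    diff = aa != bb
    if model == "p":
        return float(diff.sum() / n), n
    transitions = int((diff & (_PURINE[aa] == _PURINE[bb])).sum())
    transversions = int(diff.sum()) - transitions
    return k2p_distance(PairCounts(P=transitions / n, Q=transversions / n, n=n)), n


def distance_matrix(dataset: MarkerDataset, model: str = "k2p") -> DistanceMatrix:
    """All pairwise distances for an aligned dataset.

    Parameters
    ----------
    model : ``"p"`` or ``"k2p"``.
    """
    if model not in ("p", "k2p"):
        raise ValueError(f"unknown model {model!r}")
    if len(dataset) < 2:
        raise ValueError("distance matrix requires >= 2 sequences")
    if not dataset.aligned:
        raise ValueError("distance matrix requires an aligned dataset")
    encoded = [_encode(r.sequence) for r in dataset]
    n = len(encoded)
    values = np.zeros((n, n))
    sites = np.zeros((n, n), dtype=int)
    for i in range(n):
        sites[i, i] = int((encoded[i] != 255).sum())
        for j in range(i + 1, n):
            try:
                d, ns = _pair_distance(encoded[i], encoded[j], model)
            except ValueError as exc:
                raise ValueError(
                    f"pair ({dataset.records[i].sample_id!r}, "
                    f"{dataset.records[j].sample_id!r}): {exc}"
                ) from exc
            values[i, j] = values[j, i] = d
            sites[i, j] = sites[j, i] = ns
    return DistanceMatrix(
        ids=dataset.sample_ids, model=model, values=values, comparable_sites=sites
    )


def bootstrap_se(
    dataset: MarkerDataset,
    model: str = "k2p",
    replicates: int = 1000,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Site-bootstrap standard errors for every pairwise distance.

    Alignment columns are resampled with replacement per replicate and the
    distance recomputed; the SE is the standard deviation over replicates.
    Replicates in which a pair has no comparable sites (or a saturated K2P
    value) are skipped for that pair and counted in ``n_skipped``.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    encoded = np.vstack([_encode(r.sequence) for r in dataset])
    n_seq, length = encoded.shape
    pairs = [(i, j) for i in range(n_seq) for j in range(i + 1, n_seq)]
    reps: dict[tuple[int, int], list[float]] = {p: [] for p in pairs}
    skipped = {p: 0 for p in pairs}
    for _ in range(replicates):
        cols = rng.integers(0, length, size=length)
        sample = encoded[:, cols]
        for i, j in pairs:
            try:
                d, _ = _pair_distance(sample[i], sample[j], model)
            except ValueError:
                skipped[(i, j)] += 1
                continue
            if np.isnan(d):
                skipped[(i, j)] += 1
                continue
            reps[(i, j)].append(d)
    ids = dataset.sample_ids
    rows = []
    for (i, j), dists in reps.items():
        rows.append(
            {
                "id_a": ids[i],
                "id_b": ids[j],
                "model": model,
                "se": float(np.std(dists, ddof=0)) if dists else float("nan"),
                "n_replicates": len(dists),
                "n_skipped": skipped[(i, j)],
            }
        )
    return pd.DataFrame(rows)
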