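"""Pairwise F84 phylogenetic distances from a DNA alignment.

The F84 substitution model allows unequal base frequencies and separate
transition/transversion rates and admits a closed-form maximum-likelihood
pairwise distance.  With transition proportion P, transversion proportion Q
and empirical frequencies pi (purine sum piR = piA + piG, pyrimidine sum
piY = piC + piT),

    A = piC*piT/piY + piA*piG/piR
    B = piC*piT + piA*piG
    C = piR*piY

    d = -2A ln(1 - P/(2A) - (A - B) Q/(2AC)) + 2(A - B - C) ln(1 - Q/(2C))

which reduces to the K80 two-parameter formula at equal frequencies.  Sites
with a gap or ambiguity in either sequence of a pair are excluded pairwise.
Bootstrap confidence intervals resample alignment columns with replacement.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio import SeqIO

_VALID = {"A": 0, "C": 1, "G": 2, "T": 3}


@dataclass
class Alignment:
    """Aligned sequences over {A, C, G, T, -, N}; rows share one length."""

    names: list
    codes: np.ndarray     # (taxa, sites) int8; 0..3 = ACGT, -1 = gap/ambiguous

    def __post_init__(self):
        if len(self.names) < 2:
            raise ValueError("alignment needs at least two taxa")
        if len(set(self.names)) != len(self.names):
            raise ValueError("duplicate taxon names")
        if self.codes.shape[0] != len(self.names):
            raise ValueError("row count must match name count")

    @classmethod
    def from_sequences(cls, mapping: dict) -> "Alignment":
        names = list(mapping)
        lengths = {len(s) for s in mapping.values()}
        if len(lengths) != 1:
            raise ValueError("sequences must have equal aligned length")
        codes = np.full((len(names), lengths.pop()), -1, dtype=np.int8)
        for i, name in enumerate(names):
            for j, ch in enumerate(str(mapping[name]).upper()):
                codes[i, j] = _VALID.get(ch, -1)
        return cls(names, codes)

    @classmethod
    def from_fasta(cls, path) -> "Alignment":
        # file convention: underscores in ids stand for spaces in taxon names
        recs = {r.id.replace("_", " "): str(r.seq)
                for r in SeqIO.parse(str(path), "fasta")}
        if not recs:
            raise ValueError(f"no sequences in {path}")
        return cls.from_sequences(recs)

    def to_fasta(self, path) -> None:
        alpha = np.array(list("ACGT-"))
        with open(path, "w") as fh:
            for name, row in zip(self.names, self.codes):
                seq = "".join(alpha[np.where(row < 0, 4, row)])
                fh.write(f">{name.replace(' ', '_')}\n{seq}\n")

    @property
    def n_sites(self):
        return self.codes.shape[1]

    def base_frequencies(self) -> np.ndarray:
        """Empirical ACGT frequencies over the whole alignment."""
        valid = self.codes[self.codes >= 0]
        counts = np.bincount(valid, minlength=4).astype(float)
        if counts.sum() == 0:
            raise ValueError("alignment has no unambiguous bases")
        return counts / counts.sum()


@dataclass
class DistanceMatrix:
    """Symmetric non-negative distances with zero diagonal."""

    labels: list
    values: np.ndarray
    rescaled: bool = False

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape must match label count")
        finite = np.isfinite(v)
        if not np.allclose(v[finite], v.T[finite], atol=1e-12):
            raise ValueError("matrix must be symmetric")
        if not np.allclose(np.diag(v), 0.0):
            raise ValueError("diagonal must be zero")
        self.values = v

    def offdiag(self) -> np.ndarray:
        iu = np.triu_indices(len(self.labels), 1)
        return self.values[iu]


def pair_proportions(a: np.ndarray, b: np.ndarray):
    """Transition/transversion proportions over pairwise-complete sites."""
    ok = (a >= 0) & (b >= 0)
    n = int(ok.sum())
    if n == 0:
        raise ValueError("no comparable sites for this pair")
    aa, bb = a[ok], b[ok]
    diff = aa != bb
    both_purine = np.isin(aa, (0, 2)) & np.isin(bb, (0, 2))
    both_pyrim = np.isin(aa, (1, 3)) & np.isin(bb, (1, 3))
    transitions = int((diff & (both_purine | both_pyrim)).sum())
    transversions = int(diff.sum()) - transitions
    return transitions / n, transversions / n, n


def f84_distance_from_pq(P: float, Q: float, freqs) -> float:
    """Closed-form F84 ML distance from observed P, Q and base frequencies.

    Returns inf when the log arguments are non-positive (saturation).
    """
    piA, piC, piG, piT = np.asarray(freqs, dtype=float)
    piR, piY = piA + piG, piC + piT
    A = piC * piT / piY + piA * piG / piR
    B = piC * piT + piA * piG
    C = piR * piY
    arg1 = 1.0 - P / (2.0 * A) - (A - B) * Q / (2.0 * A * C)
    arg2 = 1.0 - Q / (2.0 * C)
    if arg1 <= 0 or arg2 <= 0:
        return float("inf")
    d = -2.0 * A * np.log(arg1) + 2.0 * (A - B - C) * np.log(arg2)
    return float(max(d, 0.0))


def f84_distance(seq_a, seq_b, base_frequencies=None) -> float:
    """F84 distance between two aligned coded sequences (subs/site)."""
    a = np.asarray(seq_a, dtype=np.int8)
    b = np.asarray(seq_b, dtype=np.int8)
    if base_frequencies is None:
        ok = (a >= 0) & (b >= 0)
        counts = (np.bincount(a[ok], minlength=4)
                  + np.bincount(b[ok], minlength=4)).astype(float)
        base_frequencies = counts / counts.sum()
    P, Q, _ = pair_proportions(a, b)
    return f84_distance_from_pq(P, Q, base_frequencies)


def distance_matrix(alignment: Alignment,
                    frequencies: np.ndarray | None = None) -> DistanceMatrix:
    """All-pairs F84 matrix; frequencies default to the whole alignment."""
    freqs = (alignment.base_frequencies() if frequencies is None
             else np.asarray(frequencies, dtype=float))
    k = len(alignment.names)
    d = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            d[i, j] = d[j, i] = f84_distance(alignment.codes[i],
                                             alignment.codes[j], freqs)
    return DistanceMatrix(list(alignment.names), d)


def bootstrap_distances(alignment: Alignment, n_reps: int = 1000,
                        seed: int | None = None,
                        ci: tuple = (2.5, 97.5)):
    """Column-bootstrap percentile CIs for every pair.

    Returns ``(lower, upper, n_skipped)`` DistanceMatrix-shaped arrays; a
    replicate with zero comparable sites for a pair is skipped for that pair
    (count recorded in ``n_skipped``).
    """
    rng = np.random.default_rng(seed)
    k = len(alignment.names)
    n_sites = alignment.n_sites
    freqs = alignment.base_frequencies()
    reps = np.full((n_reps, k, k), np.nan)
    reps[:, np.arange(k), np.arange(k)] = 0.0
    skipped = np.zeros((k, k), dtype=int)
    for r in range(n_reps):
        cols = rng.integers(0, n_sites, n_sites)
        codes = alignment.codes[:, cols]
        for i in range(k):
            for j in range(i + 1, k):
                try:
                    d = f84_distance(codes[i], codes[j], freqs)
                except ValueError:
                    skipped[i, j] += 1
                    skipped[j, i] += 1
                    continue
                reps[r, i, j] = reps[r, j, i] = d
    with np.errstate(invalid="ignore"):
        lower = np.nanpercentile(reps, ci[0], axis=0)
        upper = np.nanpercentile(reps, ci[1], axis=0)
    np.fill_diagonal(lower, 0.0)
    np.fill_diagonal(upper, 0.0)
    return lower, upper, skipped


def rescale_distance(matrix: DistanceMatrix) -> DistanceMatrix:
    """Linear min-max rescale of the off-diagonal entries to [0, 1]."""
    off = matrix.offdiag()
    lo, hi = off.min(), off.max()
    if hi == lo:
        raise ValueError("all off-diagonal distances equal; "
                         "rescaling undefined")
    v = (matrix.values - lo) / (hi - lo)
    np.fill_diagonal(v, 0.0)
    return DistanceMatrix(list(matrix.labels), v, rescaled=True)


def f84_rate_matrix(freqs, kappa: float = 2.0) -> np.ndarray:
    """Normalised F84 instantaneous rate matrix (expected 1 sub/site/unit).

    Off-diagonal rate i->j is pi_j for transversions and
    pi_j * (1 + kappa/pi_group(j)) for transitions, with pi_group the purine
    or pyrimidine frequency sum of the target base.
    """
    pi = np.asarray(freqs, dtype=float)
    piR, piY = pi[0] + pi[2], pi[1] + pi[3]
    group = np.array([piR, piY, piR, piY])
    Q = np.tile(pi, (4, 1))
    for i in range(4):
        for j in range(4):
            if i == j:
                continue
            transition = (i, j) in ((0, 2), (2, 0), (1, 3), (3, 1))
            if transition:
                Q[i, j] = pi[j] * (1.0 + kappa / group[j])
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    rate = -(pi * np.diag(Q)).sum()
    return Q / rate


# ------------------------------------------------------------- PHYLIP I/O

def write_phylip(matrix: DistanceMatrix, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"{len(matrix.labels)}\n")
        for name, row in zip(matrix.labels, matrix.values):
            safe = name.replace(" ", "_")[:30]
            fh.write(f"{safe:<32s}" + "  ".join(f"{v:.6f}" for v in row)
                     + "\n")


def read_phylip(path) -> DistanceMatrix:
    with open(path) as fh:
        tokens = fh.read().split("\n")
    k = int(tokens[0].strip())
    labels, rows = [], []
    for line in tokens[1:]:
        if not line.strip():
            continue
        parts = line.split()
        labels.append(parts[0].replace("_", " "))
        rows.append([float(v) for v in parts[1:]])
    if len(labels) != k:
        raise ValueError(f"expected {k} taxa, found {len(labels)}")
    return DistanceMatrix(labels, np.array(rows))
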