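"""Equal-frequency discretization, plug-in entropy and mutual information.

Every microorganism x gene pair is scored with the plug-in (maximum
likelihood) mutual information of the two discretized vectors,

    MI(X, Y) = H(X) + H(Y) - H(X, Y),   H(Z) = -sum_b p_b ln p_b,

with empirical cell probabilities from the joint contingency table.  MI is
reported in nats by default (bits = nats / ln 2).  Discretization uses
equal-frequency (empirical quantile) bin edges with value-based assignment,
so tied values always share a bin and any strictly increasing transform of
the raw values leaves the codes — and hence MI — unchanged.

The default bin count follows the cube-root convention,
``nbins = ceil(n ** (1/3))`` for n samples.  The rule assigning one bin per
observation is available as ``bin_rule="n-obs"`` for audit; with all-distinct
values it makes every marginal uniform over n singleton bins and the MI of
every all-distinct pair degenerate at ln n, so it is not the default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from migenet.containers import AlignmentError, OmicsMatrix

BIN_RULES = ("cube-root", "n-obs")


def default_nbins(n_samples: int, rule: str = "cube-root") -> int:
    """Bin count for ``n_samples`` observations under the named rule."""
    if rule == "cube-root":
        return max(2, math.ceil(n_samples ** (1.0 / 3.0)))
    if rule == "n-obs":
        return n_samples
    raise ValueError(f"unknown bin rule {rule!r}; expected one of {BIN_RULES}")


@dataclass
class DiscretizedVector:
    """Integer bin codes for one feature vector.

    ``nbins`` is the requested bin count; under heavy ties duplicate
    quantile edges collapse, so the number of occupied bins
    (``effective_nbins``) may be smaller.
    """

    codes: np.ndarray
    nbins: int

    @property
    def n(self) -> int:
        return self.codes.size

    @property
    def arity(self) -> int:
        """Smallest k such that every code is in [0, k)."""
        return int(self.codes.max()) + 1 if self.codes.size else 0

    @property
    def effective_nbins(self) -> int:
        return int(np.unique(self.codes).size)


def discretize_equal_frequency(values, nbins: int) -> DiscretizedVector:
    """Assign each observation to an equal-frequency (quantile) bin.

    Bin edges are the j/nbins empirical quantiles (nearest-rank order
    statistics, j = 1..nbins-1); assignment is by value into right-closed
    intervals, so tied values always share a bin.  Duplicate edges are
    collapsed, which under heavy ties (e.g. zero inflation) yields fewer
    than ``nbins`` occupied bins.
    """
    x = np.asarray(values, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("cannot discretize an empty vector")
    if not np.isfinite(x).all():
        raise ValueError("values must be finite")
    if not (1 <= nbins <= x.size):
        raise ValueError(f"need 1 <= nbins <= n ({nbins=}, n={x.size})")
    if nbins == 1:
        return DiscretizedVector(np.zeros(x.size, dtype=np.int64), 1)
    qs = np.arange(1, nbins) / nbins
    # inverted_cdf = nearest-rank order statistic: equivariant under any
    # strictly increasing transform, unlike interpolating quantiles
    edges = np.unique(np.quantile(x, qs, method="inverted_cdf"))
    codes = np.searchsorted(edges, x, side="left").astype(np.int64)
    return DiscretizedVector(codes, nbins)


def entropy_empirical(d: DiscretizedVector) -> float:
    """Plug-in Shannon entropy of the empirical code distribution, in nats."""
    codes = np.asarray(d.codes)
    if codes.size == 0:
        raise ValueError("empty code vector")
    counts = np.bincount(codes)
    p = counts[counts > 0] / codes.size
    return float(-(p * np.log(p)).sum())


def _joint_entropy(x: np.ndarray, y: np.ndarray, ax: int, ay: int) -> float:
    counts = np.bincount(x * ay + y, minlength=ax * ay)
    p = counts[counts > 0] / x.size
    return float(-(p * np.log(p)).sum())


def mutual_information(x: DiscretizedVector, y: DiscretizedVector) -> float:
    """Plug-in mutual information of two discretized vectors, in nats.

    MI = H(X) + H(Y) - H(X,Y) over the observed joint contingency table.
    Tiny negative values from floating-point cancellation (|MI| <= 1e-12)
    are clamped to zero.
    """
    if x.n != y.n:
        raise AlignmentError(f"length mismatch: {x.n} vs {y.n}")
    hx = entropy_empirical(x)
    hy = entropy_empirical(y)
    # canonical argument order makes the float result exactly symmetric
    if (x.arity, x.codes.tobytes()) > (y.arity, y.codes.tobytes()):
        x, y = y, x
    hxy = _joint_entropy(x.codes, y.codes, x.arity, y.arity)
    mi = hx + hy - hxy
    return mi if mi > 0.0 else 0.0


@dataclass
class MIResult:
    """Pairwise mutual information for every microbe x gene pair.

    ``mi[i, j]`` is the MI between the i-th microbe and the j-th gene, in
    ``unit`` (nats or bits).
    """

    microbe_ids: list[str]
    gene_ids: list[str]
    mi: np.ndarray
    nbins_used: int
    unit: str = "nats"

    def __post_init__(self) -> None:
        if self.unit not in ("nats", "bits"):
            raise ValueError("unit must be 'nats' or 'bits'")
        if self.mi.shape != (len(self.microbe_ids), len(self.gene_ids)):
            raise ValueError("mi matrix shape does not match id lists")

    def to_unit(self, unit: str) -> "MIResult":
        if unit == self.unit:
            return self
        # bits = nats / ln 2 exactly (division, not reciprocal multiply)
        if unit == "bits":
            converted = self.mi / math.log(2.0)
        else:
            converted = self.mi * math.log(2.0)
        return MIResult(self.microbe_ids, self.gene_ids, converted,
                        self.nbins_used, unit)

    def to_long_frame(self):
        """Long-format (microbe_id, gene_id, mi) DataFrame, row-major order."""
        import pandas as pd

        mi_idx = np.repeat(np.arange(len(self.microbe_ids)), len(self.gene_ids))
        gi_idx = np.tile(np.arange(len(self.gene_ids)), len(self.microbe_ids))
        return pd.DataFrame({
            "microbe_id": np.asarray(self.microbe_ids, dtype=object)[mi_idx],
            "gene_id": np.asarray(self.gene_ids, dtype=object)[gi_idx],
            "mi": self.mi.ravel(),
        })

    def to_dense_frame(self):
        import pandas as pd

        return pd.DataFrame(self.mi, index=self.microbe_ids, columns=self.gene_ids)


def pairwise_mi(
    microbes: OmicsMatrix,
    genes: OmicsMatrix,
    nbins: int | None = None,
    unit: str = "nats",
    bin_rule: str = "cube-root",
    gene_chunk: int = 2048,
) -> MIResult:
    """Mutual information for every microbe x gene pair.

    Each feature is discretized once and reused across all its pairs; joint
    contingency tables are accumulated in gene chunks so memory stays
    bounded by ``gene_chunk * nbins**2`` regardless of the total number of
    pairs.  Deterministic: no randomness is involved.
    """
    microbes.check_aligned(genes)
    n = microbes.n_samples
    if nbins is None:
        nbins = default_nbins(n, bin_rule)
    if nbins < 2:
        raise ValueError("pairwise MI needs nbins >= 2")

    m_disc = [discretize_equal_frequency(row, nbins) for row in microbes.values]
    g_disc = [discretize_equal_frequency(row, nbins) for row in genes.values]
    m_h = np.array([entropy_empirical(d) for d in m_disc])
    g_h = np.array([entropy_empirical(d) for d in g_disc])

    ag = max((d.arity for d in g_disc), default=1)
    g_codes = np.vstack([d.codes for d in g_disc]) if g_disc else np.empty((0, n), int)

    out = np.zeros((microbes.n_features, genes.n_features))
    logn = math.log(n)
    for i, dx in enumerate(m_disc):
        ax = dx.arity
        base = dx.codes[np.newaxis, :] * ag  # joint cell = x*ag + y
        ncells = ax * ag
        for lo in range(0, genes.n_features, gene_chunk):
            hi = min(lo + gene_chunk, genes.n_features)
            chunk = g_codes[lo:hi]
            flat = (np.arange(hi - lo)[:, np.newaxis] * ncells + base + chunk).ravel()
            counts = np.bincount(flat, minlength=(hi - lo) * ncells)
            counts = counts.reshape(hi - lo, ncells)
            with np.errstate(divide="ignore", invalid="ignore"):
                contrib = counts * (np.log(counts, where=counts > 0,
                                           out=np.zeros(counts.shape)))
            hxy = logn - contrib.sum(axis=1) / n
            out[i, lo:hi] = m_h[i] + g_h[lo:hi] - hxy
    np.clip(out, 0.0, None, out=out)

    result = MIResult(microbes.feature_ids, genes.feature_ids, out, nbins, "nats")
    return result.to_unit(unit)
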