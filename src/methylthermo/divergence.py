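"""Per-site methylation levels and information divergences.

Each cytosine site carries a two-outcome (methylated / unmethylated)
distribution.  A sample is compared against a reference — another sample
or the pooled-count centroid of a control group — by a symmetric
divergence of the two Bernoulli distributions:

* Jeffreys (J-) divergence, the symmetrized Kullback–Leibler divergence,
  reported in bits (log base 2); the default throughout the package.
* Hellinger divergence, optionally coverage-weighted.

Levels are shrunken with a pseudo-count (default 0.5, the Jeffreys prior)
so that divergences stay finite at fully (un)methylated sites.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .errors import EmptyTrackError
from .io import KEY_COLUMNS, MethylomeSample, SiteMatrix, align_samples

DivergenceKind = Literal["jeffreys", "hellinger"]

#: default pseudo-count added to both outcomes (Jeffreys prior)
DEFAULT_SHRINKAGE = 0.5


@dataclass
class DivergenceTrack:
    """Per-site divergence χ of one sample against a reference, in bits."""

    sample_id: str
    reference_id: str
    divergence_kind: DivergenceKind
    records: pd.DataFrame  # columns: chromosome, position, strand, chi
    log_base: int = 2

    @property
    def chi(self) -> np.ndarray:
        return self.records["chi"].to_numpy()

    def __len__(self) -> int:
        return len(self.records)

    def quantile(self, q: float) -> float:
        """Empirical quantile of χ (e.g. q=0.95 for a background cutoff)."""
        return float(np.quantile(self.chi, q))

    def to_tsv(self, path) -> None:
        out = self.records.copy()
        out.insert(0, "reference", self.reference_id)
        out.insert(0, "sample", self.sample_id)
        out = out.rename(columns={"chi": "chi_bits"})
        out.to_csv(path, sep="\t", index=False)


def methylation_level(
    methylated, unmethylated, shrinkage: float = DEFAULT_SHRINKAGE
):
    """Estimated methylation level (m + s) / (m + u + 2s).

    With ``shrinkage=0`` this is the plain read proportion m/(m+u).
    Zero-coverage sites give NaN (missing).  Accepts scalars or arrays.
    """
    m = np.asarray(methylated, dtype=float)
    u = np.asarray(unmethylated, dtype=float)
    if shrinkage < 0:
        raise ValueError("shrinkage must be non-negative")
    if (m < 0).any() or (u < 0).any():
        raise ValueError("counts must be non-negative")
    total = m + u
    with np.errstate(invalid="ignore", divide="ignore"):
        level = np.where(total > 0, (m + shrinkage) / (total + 2 * shrinkage), np.nan)
    if level.ndim == 0:
        return float(level)
    return level


def jeffreys_divergence(p, q):
    """Jeffreys (J-) divergence of two Bernoulli levels, in bits.

    χ = (p − q)·[log₂(p/q) − log₂((1−p)/(1−q))] — the symmetrized KL
    divergence KL(P‖Q) + KL(Q‖P) of the two-outcome methylation variable.
    Requires p, q strictly inside (0, 1); use a positive shrinkage when
    estimating levels from counts.
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if ((p <= 0) | (p >= 1) | (q <= 0) | (q >= 1)).any():
        raise ValueError(
            "levels must lie strictly in (0, 1); estimate them with a "
            "positive shrinkage pseudo-count"
        )
    chi = (p - q) * (np.log2(p / q) - np.log2((1 - p) / (1 - q)))
    # clip tiny negative round-off at p ≈ q
    chi = np.maximum(chi, 0.0)
    if chi.ndim == 0:
        return float(chi)
    return chi


def hellinger_divergence(p, q, n1=None, n2=None, weighted: bool = False):
    """Squared-Hellinger-type divergence of two Bernoulli levels.

    Unweighted: (√p − √q)² + (√(1−p) − √(1−q))², bounded in [0, 2].
    Weighted: multiplied by w = 2·n1·n2/(n1 + n2), the harmonic-mean
    coverage factor that puts the statistic on a chi-squared-like scale.
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if ((p < 0) | (p > 1) | (q < 0) | (q > 1)).any():
        raise ValueError("levels must lie in [0, 1]")
    h = (np.sqrt(p) - np.sqrt(q)) ** 2 + (np.sqrt(1 - p) - np.sqrt(1 - q)) ** 2
    if weighted:
        if n1 is None or n2 is None:
            raise ValueError("weighted divergence requires coverages n1 and n2")
        n1 = np.asarray(n1, dtype=float)
        n2 = np.asarray(n2, dtype=float)
        if ((n1 + n2) <= 0).any():
            raise ValueError("weighted divergence requires n1 + n2 > 0")
        h = h * (2.0 * n1 * n2 / (n1 + n2))
    if h.ndim == 0:
        return float(h)
    return h


def group_centroid(
    samples: Sequence[MethylomeSample], sample_id: str = "centroid"
) -> MethylomeSample:
    """Pooled-count centroid of a control group.

    At each site of the intersection across samples, counts are summed
    element-wise, so the centroid level is the pooled proportion.
    """
    if len(samples) == 0:
        raise ValueError("need at least one sample")
    if len(samples) == 1:
        s = samples[0]
        return MethylomeSample(sample_id, s.sites, group_label=s.group_label)
    matrix = align_samples(samples)
    if matrix.counts.empty:
        warnings.warn("group_centroid: empty intersection, empty reference", stacklevel=2)
        empty = samples[0].sites.iloc[0:0]
        return MethylomeSample(sample_id, empty)
    meth = sum(matrix.counts[(sid, "n_meth")] for sid in matrix.sample_ids)
    unmeth = sum(matrix.counts[(sid, "n_unmeth")] for sid in matrix.sample_ids)
    df = matrix.counts.index.to_frame(index=False)
    df["context"] = "other"
    df["n_meth"] = meth.to_numpy()
    df["n_unmeth"] = unmeth.to_numpy()
    return MethylomeSample(sample_id, df, group_label="centroid")


def divergence_track(
    sample: MethylomeSample,
    reference: MethylomeSample,
    kind: DivergenceKind = "jeffreys",
    shrinkage: float = DEFAULT_SHRINKAGE,
    weighted: bool = False,
) -> DivergenceTrack:
    """Per-site divergence χ of ``sample`` against ``reference``.

    Levels are estimated with the given shrinkage on both samples; sites
    with zero coverage in either sample are dropped, not imputed.
    """
    matrix: SiteMatrix = align_samples([sample, reference])
    if matrix.counts.empty:
        raise EmptyTrackError(
            f"no shared sites between {sample.sample_id!r} and "
            f"{reference.sample_id!r}"
        )
    c = matrix.counts
    m1 = c[(sample.sample_id, "n_meth")].to_numpy(float)
    u1 = c[(sample.sample_id, "n_unmeth")].to_numpy(float)
    m2 = c[(reference.sample_id, "n_meth")].to_numpy(float)
    u2 = c[(reference.sample_id, "n_unmeth")].to_numpy(float)
    n1, n2 = m1 + u1, m2 + u2
    covered = (n1 > 0) & (n2 > 0)

    p = methylation_level(m1[covered], u1[covered], shrinkage)
    q = methylation_level(m2[covered], u2[covered], shrinkage)
    if kind == "jeffreys":
        chi = jeffreys_divergence(p, q)
    elif kind == "hellinger":
        chi = hellinger_divergence(
            p, q, n1[covered], n2[covered], weighted=weighted
        )
    else:
        raise ValueError(f"unknown divergence kind {kind!r}")

    records = c.index.to_frame(index=False).loc[covered].reset_index(drop=True)
    records["chi"] = chi
    return DivergenceTrack(
        sample_id=sample.sample_id,
        reference_id=reference.sample_id,
        divergence_kind=kind,
        records=records,
    )


def mean_divergence(
    track: DivergenceTrack, by: Literal["chromosome", "genome"] = "chromosome"
) -> pd.Series:
    """Mean divergence ⟨χ⟩ per chromosome or for the whole genome.

    ⟨χ⟩ is the ν of the fluctuation analysis.  Returns a Series indexed
    by chromosome (or the single index ``genome``).
    """
    if len(track) == 0:
        raise EmptyTrackError("empty divergence track")
    if by == "genome":
        return pd.Series({"genome": float(track.records["chi"].mean())})
    if by == "chromosome":
        return track.records.groupby("chromosome", sort=True)["chi"].mean()
    raise ValueError(f"unknown stratification {by!r}")
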