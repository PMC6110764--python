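"""Fixed-size protein descriptors by two-dimensional PCA.

Ordinary PCA flattens each sample into a long vector before computing a
covariance matrix; two-dimensional PCA (2DPCA) instead works on the matrix
samples directly. For 20-column profile matrices V_1 ... V_N it accumulates
the 20 x 20 total scatter matrix

    G_t = (1/N) * sum_i (V_i - Vbar)^T (V_i - Vbar)

and projects each (centered) matrix onto the leading eigenvectors
X_1 ... X_d of G_t: F_k = (V - Vbar) X_k. The concatenated projections form
a fixed-length descriptor of the protein, and the concatenation of two
protein descriptors describes a candidate interacting pair.

PSSMs have a variable number of rows (one per residue), while the scatter
sum above needs same-shape samples. The default standardisation maps an
N x 20 profile M to its length-normalised Gram matrix A = M^T M / N, which
is 20 x 20 for every protein and stable under protein length; padding or
truncating rows to a fixed count is available as an alternative.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .pssm_io import PSSM

__all__ = [
    "TwoDPCAConfig",
    "FixedMatrix",
    "ProjectionBasis",
    "FeatureVector",
    "PairFeature",
    "pssm_to_fixed",
    "fit_2dpca",
    "project",
    "pair_feature",
]

_ORTHO_TOL = 1e-8


@dataclass(frozen=True)
class TwoDPCAConfig:
    """Descriptor-extraction settings.

    d : number of retained projection axes (1..20; default 20, the full
        basis, which makes projection an isometry).
    fixed_transform : "gram" (A = M^T M / N) or "pad_truncate:<N>"
        (rows padded with zeros / truncated to N before use).
    center : subtract the training mean matrix before projecting.
    sigmoid : squash raw log-odds through 1/(1+exp(-x)) before the fixed
        transform; off by default (raw scores).
    """

    d: int = 20
    fixed_transform: str = "gram"
    center: bool = True
    sigmoid: bool = False

    def __post_init__(self) -> None:
        if not 1 <= self.d <= 20:
            raise ValueError(f"d must be in 1..20, got {self.d}")
        if self.fixed_transform != "gram":
            prefix, _, arg = self.fixed_transform.partition(":")
            if prefix != "pad_truncate" or not arg.isdigit() or int(arg) < 1:
                raise ValueError(
                    f"fixed_transform must be 'gram' or 'pad_truncate:<N>', "
                    f"got {self.fixed_transform!r}"
                )


@dataclass
class FixedMatrix:
    """A 20 x 20 standardised profile matrix (sample V_i of the scatter sum)."""

    protein_id: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (20, 20):
            raise ValueError(
                f"FixedMatrix {self.protein_id!r}: expected 20x20, "
                f"got {self.values.shape}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"FixedMatrix {self.protein_id!r}: non-finite entries")


@dataclass
class ProjectionBasis:
    """Fitted 2DPCA basis: mean matrix, scatter matrix and ordered axes.

    ``axes`` is a d x 20 array whose rows are mutually orthonormal unit
    eigenvectors of the scatter matrix, ordered by nonincreasing
    eigenvalue; each axis's first nonzero coordinate is positive so the
    basis is deterministic across platforms.
    """

    mean_matrix: np.ndarray
    axes: np.ndarray
    eigenvalues: np.ndarray
    scatter_matrix: np.ndarray
    d: int
    config: TwoDPCAConfig = field(default_factory=TwoDPCAConfig)

    def __post_init__(self) -> None:
        self.mean_matrix = np.asarray(self.mean_matrix, dtype=float)
        self.axes = np.asarray(self.axes, dtype=float)
        self.eigenvalues = np.asarray(self.eigenvalues, dtype=float)
        self.scatter_matrix = np.asarray(self.scatter_matrix, dtype=float)
        if not 1 <= self.d <= 20 or self.axes.shape != (self.d, 20):
            raise ValueError(
                f"axes shape {self.axes.shape} inconsistent with d={self.d}"
            )
        gram = self.axes @ self.axes.T
        if np.max(np.abs(gram - np.eye(self.d))) > _ORTHO_TOL:
            raise ValueError("axes are not orthonormal")
        if np.any(np.diff(self.eigenvalues) > 1e-10):
            raise ValueError("eigenvalues are not sorted nonincreasing")
        if np.any(self.eigenvalues < -1e-10):
            raise ValueError("scatter matrix has a significantly negative eigenvalue")

    @property
    def feature_length(self) -> int:
        return 20 * self.d

    def save(self, path: str | Path) -> None:
        """Serialize to a single .npz archive (bit-exact round-trip)."""
        cfg = asdict(self.config)
        np.savez(
            Path(path),
            format_version=np.array(1),
            mean_matrix=self.mean_matrix,
            axes=self.axes,
            eigenvalues=self.eigenvalues,
            scatter_matrix=self.scatter_matrix,
            d=np.array(self.d),
            config_keys=np.array(sorted(cfg), dtype=object),
            config_values=np.array([repr(cfg[k]) for k in sorted(cfg)], dtype=object),
        )

    @classmethod
    def load(cls, path: str | Path) -> "ProjectionBasis":
        with np.load(Path(path), allow_pickle=True) as z:
            if int(z["format_version"]) != 1:
                raise ValueError(
                    f"unsupported basis archive version {int(z['format_version'])}"
                )
            cfg = {
                str(k): eval(v)  # noqa: S307 - values written by save() via repr
                for k, v in zip(z["config_keys"], z["config_values"])
            }
            return cls(
                mean_matrix=z["mean_matrix"],
                axes=z["axes"],
                eigenvalues=z["eigenvalues"],
                scatter_matrix=z["scatter_matrix"],
                d=int(z["d"]),
                config=TwoDPCAConfig(**cfg),
            )


@dataclass
class FeatureVector:
    """Flattened 2DPCA descriptor of one protein (length 20*d)."""

    protein_id: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or not np.all(np.isfinite(self.values)):
            raise ValueError(
                f"FeatureVector {self.protein_id!r}: needs a finite 1-D vector"
            )


@dataclass
class PairFeature:
    """Concatenated descriptor of an ordered protein pair, optionally labelled."""

    values: np.ndarray
    label: int | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.label is not None and self.label not in (0, 1):
            raise ValueError(f"label must be 0, 1 or None, got {self.label!r}")


def pssm_to_fixed(pssm: PSSM, config: TwoDPCAConfig | None = None) -> FixedMatrix:
    """Standardise a variable-length PSSM to a 20 x 20 matrix.

    Default ("gram"): A = M^T M / N, symmetric PSD and independent of
    protein length scale. "pad_truncate:<N>" instead zero-pads or truncates
    the rows to N and is only valid when N = 20 (the sample must stay
    20 x 20 for the scatter accumulation).
    """
    config = config or TwoDPCAConfig()
    M = pssm.scores.astype(float)
    if config.sigmoid:
        M = 1.0 / (1.0 + np.exp(-M))
    if config.fixed_transform == "gram":
        A = M.T @ M / M.shape[0]
    else:
        n = int(config.fixed_transform.partition(":")[2])
        if n != 20:
            raise ValueError(
                "pad_truncate target must be 20 to keep samples 20x20"
            )
        A = np.zeros((n, 20))
        k = min(n, M.shape[0])
        A[:k] = M[:k]
    return FixedMatrix(pssm.protein_id, A)


def _fix_signs(axes: np.ndarray) -> np.ndarray:
    """Flip each axis so its first nonzero coordinate is positive."""
    out = axes.copy()
    for k in range(out.shape[0]):
        nz = np.nonzero(np.abs(out[k]) > 1e-12)[0]
        if nz.size and out[k, nz[0]] < 0:
            out[k] = -out[k]
    return out


def fit_2dpca(
    matrices: list[FixedMatrix], d: int = 20, config: TwoDPCAConfig | None = None
) -> ProjectionBasis:
    """Fit the 2DPCA projection basis from training matrices.

    Computes the mean matrix, accumulates the total scatter matrix
    G_t = (1/N) sum (V_i - Vbar)^T (V_i - Vbar), and retains the first d
    unit eigenvectors by descending eigenvalue. Deterministic: eigenvector
    signs are fixed (first nonzero coordinate positive) and the result is
    invariant to the order of the input list.
    """
    if len(matrices) < 2:
        raise ValueError(f"need at least 2 training matrices, got {len(matrices)}")
    if not 1 <= d <= 20:
        raise ValueError(f"d must be in 1..20, got {d}")
    config = config or TwoDPCAConfig(d=d)

    stack = np.stack([m.values for m in matrices])
    mean = stack.mean(axis=0)
    centered = stack - mean
    # G_t = (1/N) sum_i C_i^T C_i; einsum keeps it explicitly symmetric-summed
    g_t = np.einsum("nij,nik->jk", centered, centered) / len(matrices)
    g_t = (g_t + g_t.T) / 2.0  # clip accumulation asymmetry at machine precision

    eigvals, eigvecs = np.linalg.eigh(g_t)
    order = np.argsort(eigvals)[::-1]
    eigvals = eigvals[order]
    axes = _fix_signs(eigvecs[:, order].T[:d])

    return ProjectionBasis(
        mean_matrix=mean,
        axes=axes,
        eigenvalues=eigvals[:d],
        scatter_matrix=g_t,
        d=d,
        config=config,
    )


def project(matrix: FixedMatrix, basis: ProjectionBasis) -> FeatureVector:
    """Project a standardised matrix onto the basis axes.

    F_k = (V - Vbar) X_k for k = 1..d (centering configurable), flattened
    component-major: F_1's 20 entries first, then F_2's, and so on. With
    the full basis (d = 20) the flattened vector's Euclidean norm equals
    the Frobenius norm of V - Vbar.
    """
    V = matrix.values
    if V.shape != (20, 20):
        raise ValueError(f"expected 20x20 matrix, got {V.shape}")
    if basis.config.center:
        V = V - basis.mean_matrix
    # F[:, k] = V @ X_k; transpose -> component-major flattening
    F = V @ basis.axes.T
    return FeatureVector(matrix.protein_id, F.T.reshape(-1))


def pair_feature(
    fa: FeatureVector, fb: FeatureVector, label: int | None = None
) -> PairFeature:
    """Concatenate two protein descriptors in pair-list order [fa || fb]."""
    if fa.values.shape != fb.values.shape:
        raise ValueError(
            f"feature length mismatch: {fa.values.shape[0]} vs {fb.values.shape[0]}"
        )
    return PairFeature(np.concatenate([fa.values, fb.values]), label=label)
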