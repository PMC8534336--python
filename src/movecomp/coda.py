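"""Compositional geometry for 24-h movement behaviours.

A day's movement behaviour is treated as a composition: a vector of
strictly positive parts (sedentary behaviour, light physical activity,
moderate-to-vigorous physical activity) carrying only relative
information, closed to a declared total (600 min of monitored daytime by
default, 1440 min for a full day, or 1 for proportions).

The module provides the Aitchison-geometry primitives the downstream
regression needs: closure, zero replacement, the geometric-mean
("central") composition, the pairwise log-ratio variation matrix, the
isometric log-ratio (ilr) transform and its inverse, and pairwise time
reallocation on the raw-minute scale.

The math is written for D parts; the rest of the package surfaces D = 3
with the fixed part order (SB, LPA, MVPA).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PARTS",
    "BehaviourComposition",
    "InfeasibleReallocationError",
    "close",
    "zero_replace",
    "geometric_mean_composition",
    "variation_matrix",
    "ilr",
    "ilr_inverse",
    "reallocate",
    "ilr_basis_from_sbp",
    "default_ilr_basis",
    "DEFAULT_SBP",
    "ilr_covariance_from_variation",
]

#: Fixed part order used throughout the package.
PARTS = ("sb", "lpa", "mvpa")

#: Default epsilon for zero replacement: half of one 10-s epoch, in minutes.
DEFAULT_ZERO_EPSILON = 1.0 / 12.0

#: Default sequential binary partition: {SB | LPA, MVPA} then {LPA | MVPA}.
#: Row k splits the parts still in play into a +1 group and a -1 group
#: (0 = not involved).  The first balance contrasts sedentary time against
#: both activity intensities, the second contrasts light against
#: moderate-to-vigorous activity.
DEFAULT_SBP = np.array([[1, -1, -1], [0, 1, -1]], dtype=float)


class InfeasibleReallocationError(ValueError):
    """Raised when a raw-minute reallocation would empty or overdraw a part.

    Attributes
    ----------
    deficit : float
        How many minutes the donor part is short of the requested delta.
    """

    def __init__(self, message: str, deficit: float = 0.0):
        super().__init__(message)
        self.deficit = deficit


def ilr_basis_from_sbp(sbp: np.ndarray) -> np.ndarray:
    """Build the orthonormal ilr contrast matrix for a sequential binary partition.

    Parameters
    ----------
    sbp : (D-1, D) array of {+1, -1, 0}
        Each row is a binary split of (a subset of) the parts.

    Returns
    -------
    (D, D-1) array ``V`` with orthonormal columns summing to zero, so that
    ``ilr(x) = V.T @ log(x)`` (equivalently ``V.T @ clr(x)``).
    """
    sbp = np.asarray(sbp, dtype=float)
    n_bal, d = sbp.shape
    if n_bal != d - 1:
        raise ValueError(f"SBP must have D-1 rows for D parts, got {sbp.shape}")
    cols = []
    for row in sbp:
        r = np.count_nonzero(row > 0)
        s = np.count_nonzero(row < 0)
        if r == 0 or s == 0:
            raise ValueError("each SBP row needs a non-empty +group and -group")
        col = np.zeros(d)
        col[row > 0] = np.sqrt(s / (r * (r + s)))
        col[row < 0] = -np.sqrt(r / (s * (r + s)))
        cols.append(col)
    v = np.column_stack(cols)
    if not np.allclose(v.T @ v, np.eye(d - 1), atol=1e-12):
        raise ValueError("SBP does not define an orthonormal basis")
    return v


def default_ilr_basis(d: int = 3) -> np.ndarray:
    """Contrast matrix of the package's default ilr basis (D = 3 only)."""
    if d != 3:
        raise NotImplementedError("only 3-part compositions are surfaced")
    return ilr_basis_from_sbp(DEFAULT_SBP)


@dataclass(frozen=True)
class BehaviourComposition:
    """Strictly positive behaviour parts with a declared total.

    ``parts`` holds (SB, LPA, MVPA) on whatever scale ``total`` declares:
    minutes per day (total 600 or 1440) or proportions (total 1).
    """

    parts: np.ndarray
    total: float = 600.0
    labels: tuple[str, ...] = field(default=PARTS, repr=False)

    def __post_init__(self):
        parts = np.asarray(self.parts, dtype=float)
        object.__setattr__(self, "parts", parts)
        if parts.ndim != 1 or parts.size != len(self.labels):
            raise ValueError(f"expected {len(self.labels)} parts, got {parts.shape}")
        if not np.all(np.isfinite(parts)) or np.any(parts <= 0):
            raise ValueError("composition parts must be finite and strictly positive")
        if self.total <= 0:
            raise ValueError("total must be positive")
        if abs(parts.sum() - self.total) > 1e-9 * max(self.total, 1.0):
            raise ValueError(
                f"parts sum to {parts.sum():.12g}, not the declared total {self.total:.12g}"
            )

    def __getitem__(self, key: str) -> float:
        return float(self.parts[self.labels.index(key)])

    def proportions(self) -> np.ndarray:
        return self.parts / self.total


def _as_parts(x) -> np.ndarray:
    if isinstance(x, BehaviourComposition):
        return x.parts
    return np.asarray(x, dtype=float)


def close(parts, total: float = 600.0) -> BehaviourComposition:
    """Linearly rescale positive parts so they sum to ``total``.

    Raises if any part is non-positive; route such data through
    :func:`zero_replace` first.
    """
    parts = _as_parts(parts)
    if total <= 0:
        raise ValueError("total must be positive")
    if np.any(parts <= 0):
        raise ValueError("closure requires strictly positive parts; apply zero_replace first")
    scaled = parts * (total / parts.sum())
    # re-normalise exactly to kill last-ulp drift
    scaled = scaled * (total / scaled.sum())
    return BehaviourComposition(scaled, total)


def zero_replace(parts, epsilon: float = DEFAULT_ZERO_EPSILON) -> np.ndarray:
    """Replace zero parts by ``epsilon``, shrinking the rest to keep the total.

    The default epsilon is half of one 10-s epoch expressed in minutes
    (1/12 min), i.e. below the resolution of the measurement.  Non-zero
    parts are reduced multiplicatively so the vector total is conserved
    (simple multiplicative replacement).
    """
    parts = np.asarray(parts, dtype=float)
    if np.any(parts < 0):
        raise ValueError("parts must be non-negative")
    total = parts.sum()
    if total <= 0:
        raise ValueError("all-zero composition cannot be repaired")
    zero = parts == 0
    if not zero.any():
        return parts.copy()
    n_zero = zero.sum()
    if n_zero * epsilon >= total:
        raise ValueError("epsilon too large: replacement would exceed the total")
    out = parts * (1.0 - n_zero * epsilon / total)
    out[zero] = epsilon
    return out


def geometric_mean_composition(compositions, total: float = 600.0) -> BehaviourComposition:
    """Component-wise geometric mean across samples, closed to ``total``.

    This is the compositional centre used as the descriptive "mean
    composition" and as the baseline for isotemporal substitution.
    """
    comps = np.atleast_2d(np.asarray(compositions, dtype=float))
    if comps.size == 0:
        raise ValueError("need at least one composition")
    if np.any(comps <= 0):
        raise ValueError("all parts must be strictly positive")
    gm = np.exp(np.log(comps).mean(axis=0))
    return close(gm, total)


def variation_matrix(compositions) -> np.ndarray:
    """Pairwise log-ratio variation matrix.

    Entry ``[i, j]`` is the sample variance (denominator n-1) of
    ``ln(part_i / part_j)`` across samples.  Symmetric, zero diagonal,
    invariant to per-sample closure.  An entry near zero means the two
    parts are nearly proportional across the sample.
    """
    comps = np.atleast_2d(np.asarray(compositions, dtype=float))
    n, d = comps.shape
    if n < 2:
        raise ValueError("variation matrix needs at least 2 samples")
    if np.any(comps <= 0):
        raise ValueError("all parts must be strictly positive")
    logc = np.log(comps)
    out = np.zeros((d, d))
    for i in range(d):
        for j in range(i + 1, d):
            v = np.var(logc[:, i] - logc[:, j], ddof=1)
            out[i, j] = out[j, i] = v
    return out


def ilr(composition, basis: np.ndarray | None = None) -> np.ndarray:
    """Isometric log-ratio coordinates of one composition or a stack.

    With the default basis, ``z1 = sqrt(2/3) * ln(SB / sqrt(LPA*MVPA))``
    (sedentary vs both activity intensities) and
    ``z2 = sqrt(1/2) * ln(LPA / MVPA)`` (light vs moderate-to-vigorous).
    Coordinates are invariant to the composition's total.

    Accepts a :class:`BehaviourComposition`, a length-D vector, or an
    (n, D) array; returns a length-(D-1) vector or (n, D-1) array.
    """
    x = _as_parts(composition)
    if np.any(x <= 0):
        raise ValueError("ilr requires strictly positive parts")
    v = default_ilr_basis(x.shape[-1]) if basis is None else np.asarray(basis, float)
    return np.log(x) @ v


def ilr_inverse(coords, total: float = 600.0, basis: np.ndarray | None = None):
    """Map ilr coordinates back to the unique composition with the given total.

    Returns a :class:`BehaviourComposition` for a single coordinate
    vector, or an (n, D) array of closed parts for a stack.
    """
    z = np.asarray(coords, dtype=float)
    if not np.all(np.isfinite(z)):
        raise ValueError("ilr coordinates must be finite")
    d = z.shape[-1] + 1
    v = default_ilr_basis(d) if basis is None else np.asarray(basis, float)
    logx = z @ v.T
    x = np.exp(logx - logx.max(axis=-1, keepdims=True))
    x = x / x.sum(axis=-1, keepdims=True) * total
    if x.ndim == 1:
        return close(x, total)
    return x


def reallocate(
    composition,
    add_to: str,
    remove_from: str,
    delta_minutes: float,
    labels: tuple[str, ...] = PARTS,
) -> BehaviourComposition:
    """Move ``delta_minutes`` from one behaviour to another, total preserved.

    Operates on the raw-minute scale: the receiving part gains delta, the
    donor loses delta, the third part is untouched.  Infeasible when the
    donor holds no more than delta (the composition must stay strictly
    positive).
    """
    comp = composition if isinstance(composition, BehaviourComposition) else BehaviourComposition(
        np.asarray(composition, float), float(np.sum(composition)), labels
    )
    if add_to == remove_from:
        raise ValueError("add_to and remove_from must differ")
    if add_to not in comp.labels or remove_from not in comp.labels:
        raise ValueError(f"behaviours must be among {comp.labels}")
    if delta_minutes < 0:
        raise ValueError("delta must be non-negative")
    parts = comp.parts.copy()
    i_add = comp.labels.index(add_to)
    i_rem = comp.labels.index(remove_from)
    if delta_minutes >= parts[i_rem]:
        raise InfeasibleReallocationError(
            f"reallocation infeasible: removing {delta_minutes:g} min from "
            f"'{remove_from}' which holds only {parts[i_rem]:g} min",
            deficit=delta_minutes - parts[i_rem],
        )
    parts[i_add] += delta_minutes
    parts[i_rem] -= delta_minutes
    return BehaviourComposition(parts, comp.total, comp.labels)


def ilr_covariance_from_variation(variation: np.ndarray, basis: np.ndarray | None = None) -> np.ndarray:
    """Convert a pairwise log-ratio variation matrix to an ilr covariance.

    Uses the standard identity linking the variation matrix T to the
    centred log-ratio covariance, Sigma_clr = -1/2 * G T G with
    G = I - J/D, then rotates into the ilr basis.  This lets a generator
    be calibrated directly to a published variation matrix.
    """
    t = np.asarray(variation, dtype=float)
    d = t.shape[0]
    if t.shape != (d, d) or not np.allclose(t, t.T):
        raise ValueError("variation matrix must be square symmetric")
    v = default_ilr_basis(d) if basis is None else np.asarray(basis, float)
    g = np.eye(d) - np.ones((d, d)) / d
    sigma_clr = -0.5 * g @ t @ g
    sigma = v.T @ sigma_clr @ v
    # symmetrise against floating-point drift and check positive definiteness
    sigma = (sigma + sigma.T) / 2
    eigvals = np.linalg.eigvalsh(sigma)
    if eigvals.min() <= 0:
        raise ValueError("variation matrix does not yield a positive-definite ilr covariance")
    return sigma
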