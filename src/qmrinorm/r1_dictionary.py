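"""MP2RAGE R1 estimation.

Two estimators working from the paired inversion-time images of an MP2RAGE
acquisition:

* **dictionary matching** — a fingerprinting-like search over a grid of
  (R1, B1) values; each dictionary entry is the unit-normalized pair of
  simulated signals (S_TI1, S_TI2), and the estimate maximizes the absolute
  inner product with the measured (unit-normalized) signal pair.  Because
  both the entries and the measurement are normalized, the estimate is
  invariant to M0 and to any global complex scaling of the data, and the B1
  dimension of the grid absorbs transmit-field inhomogeneity.
* **lookup-table inversion** — the conventional approach, inverting the
  monotone UNI(R1) curve, where UNI = S1*conj(S2)/(|S1|^2+|S2|^2).

The forward model is the steady-state solution of the MP2RAGE sequence:
adiabatic inversion, relaxation, a first GRE readout block at flip angle
alpha1*B1, relaxation, a second block at alpha2*B1, relaxation, repeated
periodically.  Signals are evaluated at the centre of each readout block
(linear k-space ordering).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger("qmrinorm")


@dataclass(frozen=True)
class MP2RAGEProtocol:
    """MP2RAGE sequence timing and flip angles.

    Times in ms, flip angles in degrees.  ``n_readout`` is the number of
    excitation pulses per GRE block and ``readout_tr`` their spacing; the
    block centre is placed at the nominal inversion times TI1/TI2.
    """

    ti1: float = 700.0
    ti2: float = 2400.0
    tr_mp2rage: float = 6000.0
    alpha1: float = 6.0
    alpha2: float = 6.0
    readout_tr: float = 7.0
    n_readout: int = 176
    inversion_efficiency: float = 0.96

    def __post_init__(self) -> None:
        if not (0.0 < self.ti1 < self.ti2 < self.tr_mp2rage):
            raise ValueError(
                f"non-physical protocol: need 0 < TI1 < TI2 < TR, got "
                f"TI1={self.ti1}, TI2={self.ti2}, TR={self.tr_mp2rage}"
            )
        for name, a in (("alpha1", self.alpha1), ("alpha2", self.alpha2)):
            if not (0.0 < a < 90.0):
                raise ValueError(f"{name} must be in (0, 90) degrees, got {a}")
        if self.n_readout < 1 or self.readout_tr <= 0:
            raise ValueError("n_readout >= 1 and readout_tr > 0 required")
        if not (0.0 < self.inversion_efficiency <= 1.0):
            raise ValueError("inversion_efficiency must be in (0, 1]")
        block = self.n_readout * self.readout_tr
        ta = self.ti1 - block / 2.0
        tb = self.ti2 - self.ti1 - block
        tc = self.tr_mp2rage - self.ti2 - block / 2.0
        if min(ta, tb, tc) < 0:
            raise ValueError(
                "non-physical protocol: readout blocks overlap the inversion "
                f"times (TA={ta:.1f}, TB={tb:.1f}, TC={tc:.1f} ms)"
            )

    @property
    def gap_times_ms(self) -> tuple[float, float, float]:
        """(TA, TB, TC): relaxation gaps before, between and after the blocks."""
        block = self.n_readout * self.readout_tr
        return (
            self.ti1 - block / 2.0,
            self.ti2 - self.ti1 - block,
            self.tr_mp2rage - self.ti2 - block / 2.0,
        )


def _relax(a, b, r1, t_ms, m0):
    """Compose free relaxation over t_ms onto the affine map mz -> a*mz + b."""
    e = np.exp(-r1 * (t_ms / 1000.0))
    return a * e, b * e + m0 * (1.0 - e)


def _gre_block(a, b, r1, cos_alpha, tr_ms, n, m0):
    """Compose n excitation pulses (flip with cos_alpha, then relax over tr_ms)."""
    e = np.exp(-r1 * (tr_ms / 1000.0))
    ce = cos_alpha * e
    cen = ce**n
    # geometric series of the per-pulse affine map
    with np.errstate(invalid="ignore", divide="ignore"):
        geo = np.where(np.abs(1.0 - ce) > 1e-12, (1.0 - cen) / (1.0 - ce), float(n))
    b_blk = m0 * (1.0 - e) * geo
    return a * cen, b * cen + b_blk


def mp2rage_forward(r1, b1=1.0, protocol: MP2RAGEProtocol | None = None, m0=1.0):
    """Steady-state MP2RAGE signals (S_TI1, S_TI2) for R1 [1/s] and B1 fraction.

    Broadcasts over array-valued ``r1``/``b1``.  Returns signed real signals
    (transverse magnetization at the two block centres times sin of the
    achieved flip angle); M0 defaults to 1 since downstream matching is
    scale-invariant.
    """
    if protocol is None:
        protocol = MP2RAGEProtocol()
    r1 = np.asarray(r1, dtype=float)
    b1 = np.asarray(b1, dtype=float)
    if np.any(r1 <= 0):
        raise ValueError("r1 must be positive")
    if np.any(b1 <= 0):
        raise ValueError("b1 must be positive")
    r1, b1 = np.broadcast_arrays(r1, b1)

    ta, tb, tc = protocol.gap_times_ms
    n = protocol.n_readout
    trr = protocol.readout_tr
    eff = protocol.inversion_efficiency
    a1 = np.deg2rad(protocol.alpha1) * b1
    a2 = np.deg2rad(protocol.alpha2) * b1
    c1, c2 = np.cos(a1), np.cos(a2)

    # one full cycle as an affine map mz -> A*mz + B, starting just before inversion
    a, b = np.full_like(r1, -eff), np.zeros_like(r1)  # inversion
    a, b = _relax(a, b, r1, ta, m0)
    a, b = _gre_block(a, b, r1, c1, trr, n, m0)
    a, b = _relax(a, b, r1, tb, m0)
    a, b = _gre_block(a, b, r1, c2, trr, n, m0)
    a, b = _relax(a, b, r1, tc, m0)
    mz_ss = b / (1.0 - a)  # steady state before inversion

    n_half = n // 2
    # propagate to the centre of block 1
    a, b = _relax(np.full_like(r1, -eff), np.zeros_like(r1), r1, ta, m0)
    a, b = _gre_block(a, b, r1, c1, trr, n_half, m0)
    mz1 = a * mz_ss + b
    s1 = np.sin(a1) * mz1
    # continue to the centre of block 2
    a, b = _gre_block(a, b, r1, c1, trr, n - n_half, m0)
    a, b = _relax(a, b, r1, tb, m0)
    a, b = _gre_block(a, b, r1, c2, trr, n_half, m0)
    mz2 = a * mz_ss + b
    s2 = np.sin(a2) * mz2
    return s1, s2


def uni_image(s1, s2):
    """The MP2RAGE UNI combination S1*conj(S2)/(|S1|^2+|S2|^2), in [-0.5, 0.5]."""
    s1 = np.asarray(s1)
    s2 = np.asarray(s2)
    denom = np.abs(s1) ** 2 + np.abs(s2) ** 2
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.real(s1 * np.conj(s2)) / denom


@dataclass
class SignalDictionary:
    """Unit-normalized simulated (S_TI1, S_TI2) pairs over an (R1, B1) grid."""

    r1_grid: np.ndarray  # [1/s], strictly increasing
    b1_grid: np.ndarray  # nominal-B1 fractions, strictly increasing
    entries: np.ndarray  # shape (n_b1, n_r1, 2), unit-norm rows
    protocol: MP2RAGEProtocol = field(default_factory=MP2RAGEProtocol)

    def b1_slice(self, b1: float) -> int:
        """Index of the nearest B1 grid slice."""
        return int(np.argmin(np.abs(self.b1_grid - b1)))


def _grid(lo: float, hi: float, step: float) -> np.ndarray:
    if step <= 0:
        raise ValueError("grid step must be positive")
    if hi < lo:
        raise ValueError("grid range is reversed")
    if step > hi - lo and hi > lo:
        raise ValueError(f"grid step {step} larger than range [{lo}, {hi}]")
    n = int(np.floor((hi - lo) / step + 0.5)) + 1
    return lo + step * np.arange(n)


def build_dictionary(
    protocol: MP2RAGEProtocol | None = None,
    r1_range: tuple[float, float] = (0.05, 4.0),
    r1_step: float = 0.005,
    b1_range: tuple[float, float] = (1.0, 1.0),
    b1_step: float = 0.005,
) -> SignalDictionary:
    """Simulate and unit-normalize MP2RAGE signal pairs over an (R1, B1) grid.

    The B1 grid step defaults to 0.005 of the nominal field; a degenerate B1
    range (single value) yields a single slice.
    """
    if protocol is None:
        protocol = MP2RAGEProtocol()
    r1_grid = _grid(*r1_range, r1_step)
    if b1_range[0] == b1_range[1]:
        b1_grid = np.array([float(b1_range[0])])
    else:
        b1_grid = _grid(*b1_range, b1_step)
    s1, s2 = mp2rage_forward(r1_grid[None, :], b1_grid[:, None], protocol)
    entries = np.stack([s1, s2], axis=-1)
    norms = np.linalg.norm(entries, axis=-1, keepdims=True)
    entries = entries / norms
    return SignalDictionary(r1_grid=r1_grid, b1_grid=b1_grid, entries=entries, protocol=protocol)


def dictionary_match(s1, s2, b1_map, dictionary: SignalDictionary):
    """Match measured (S_TI1, S_TI2) signals to the dictionary, returning R1 [1/s].

    Per voxel: the nearest B1 slice is selected, the measured 2-vector is
    normalized, and the R1 of the entry maximizing the absolute (complex)
    inner product is returned; ties break toward smaller R1.  Zero-norm
    signals yield NaN.  B1 values outside the grid are clamped (and counted
    in the log).
    """
    s1 = np.asarray(s1)
    s2 = np.asarray(s2)
    b1_map = np.asarray(b1_map, dtype=float)
    shape = s1.shape
    sig = np.stack([s1.ravel(), s2.ravel()], axis=-1)
    b1 = np.broadcast_to(b1_map, shape).ravel()

    lo, hi = dictionary.b1_grid[0], dictionary.b1_grid[-1]
    n_clamped = int(np.sum((b1 < lo) | (b1 > hi)))
    if n_clamped:
        logger.warning("dictionary_match: %d voxel(s) with B1 outside [%g, %g], clamped", n_clamped, lo, hi)
    b1 = np.clip(b1, lo, hi)
    if len(dictionary.b1_grid) > 1:
        slice_idx = np.argmin(np.abs(b1[:, None] - dictionary.b1_grid[None, :]), axis=1)
    else:
        slice_idx = np.zeros(len(b1), dtype=int)

    norms = np.linalg.norm(sig, axis=-1)
    valid = norms > 0
    n_invalid = int(np.sum(~valid))
    if n_invalid:
        logger.warning("dictionary_match: %d zero-norm voxel(s) flagged NaN", n_invalid)

    out = np.full(sig.shape[0], np.nan)
    for k in np.unique(slice_idx[valid]):
        rows = valid & (slice_idx == k)
        scores = np.abs(sig[rows] @ dictionary.entries[k].T.astype(sig.dtype))
        out[rows] = dictionary.r1_grid[np.argmax(scores, axis=1)]
    return out.reshape(shape)


def lookup_table_invert(
    uni_map,
    protocol: MP2RAGEProtocol | None = None,
    b1_map=None,
    r1_range: tuple[float, float] = (0.4, 4.0),
    n_grid: int = 2000,
):
    """Invert the monotone UNI(R1) curve by interpolation (conventional lookup).

    If ``b1_map`` is supplied, a separate curve is evaluated per B1 value
    rounded to a 0.005 grid.  UNI values outside the attainable range clamp
    to the grid ends; a non-monotone curve over ``r1_range`` raises with a
    hint to narrow the range.
    """
    if protocol is None:
        protocol = MP2RAGEProtocol()
    uni = np.asarray(uni_map, dtype=float)
    if np.any(np.abs(uni) > 0.5 + 1e-9):
        raise ValueError("UNI values must lie in [-0.5, 0.5]")
    r1_grid = np.linspace(r1_range[0], r1_range[1], n_grid)

    def invert_masked(values: np.ndarray, b1: float) -> np.ndarray:
        s1, s2 = mp2rage_forward(r1_grid, b1, protocol)
        curve = uni_image(s1, s2)
        d = np.diff(curve)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError(
                f"UNI(R1) is not monotone over R1 in [{r1_range[0]}, {r1_range[1]}] "
                f"at B1={b1}; use a narrower r1_range"
            )
        if d[0] < 0:
            return np.interp(values, curve[::-1], r1_grid[::-1])
        return np.interp(values, curve, r1_grid)

    if b1_map is None:
        return invert_masked(uni, 1.0)
    b1 = np.round(np.broadcast_to(np.asarray(b1_map, dtype=float), uni.shape) / 0.005) * 0.005
    out = np.empty_like(uni)
    for val in np.unique(b1):
        mask = b1 == val
        out[mask] = invert_masked(uni[mask], float(val))
    return out
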