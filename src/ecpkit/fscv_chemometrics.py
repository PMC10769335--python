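"""Dopamine concentration estimation from cyclic voltammograms.

Each 100 ms FSCV frame is a current-vs-applied-voltage curve (a cyclic
voltammogram, CV) recorded during the triangular −0.4 → 1.3 → −0.4 V sweep at
400 V/s.  Chemical changes are isolated by subtracting a reference frame
(background subtraction), then background-subtracted currents are projected
onto principal components trained on standards of dopamine, pH and movement
artifact.  The dopamine score maps to concentration change [ΔDA] (nM) through
a calibration regression.  Frames are nulled (declared invalid) when their
residual outside the standards' subspace exceeds a tolerance (Q > Q_alpha) or
when they correlate with a movement-artifact template at r > 0.8.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

NULL_NONE = "none"
NULL_Q = "Q_exceeded"
NULL_MOVEMENT = "movement_corr"


@dataclass
class CVStream:
    """Sequence of cyclic voltammograms.

    ``frames``: scans x points current matrix (nA); ``voltage_axis``: applied
    potential per point (V), triangular with endpoints −0.4 V and apex 1.3 V;
    ``scan_times``: frame timestamps (s) at 100 ms spacing.
    """

    frames: np.ndarray
    voltage_axis: np.ndarray
    scan_times: np.ndarray

    def __post_init__(self) -> None:
        self.frames = np.atleast_2d(np.asarray(self.frames, dtype=float))
        self.voltage_axis = np.asarray(self.voltage_axis, dtype=float)
        self.scan_times = np.asarray(self.scan_times, dtype=float)
        if self.frames.shape[0] != self.scan_times.size:
            raise ValueError("frame count must equal scan-time count")
        if self.frames.shape[1] != self.voltage_axis.size:
            raise ValueError("points per frame must match voltage axis")

    @property
    def n_scans(self) -> int:
        return self.frames.shape[0]

    @property
    def points_per_scan(self) -> int:
        return self.frames.shape[1]


@dataclass
class StandardsLibrary:
    """Principal components and calibration fitted from analyte standards."""

    components: np.ndarray  # (k, points) orthonormal rows
    coef: np.ndarray  # regression: scores -> nM
    q_alpha: float
    movement_templates: np.ndarray  # (m, points)

    def __post_init__(self) -> None:
        if self.q_alpha <= 0:
            raise ValueError("q_alpha must be positive")


@dataclass
class DATrace:
    """[ΔDA] per scan with explicit nulling of invalid frames."""

    times: np.ndarray
    delta_da: np.ndarray  # nM; NaN where nulled
    q_values: np.ndarray
    null_reason: list[str] = field(default_factory=list)

    @property
    def valid(self) -> np.ndarray:
        return np.asarray([r == NULL_NONE for r in self.null_reason])


# ---------------------------------------------------------------------------


def background_subtract(stream: CVStream, ref: int | float) -> np.ndarray:
    """ΔI matrix: every frame minus the reference frame.

    ``ref`` is a scan index, or (as a float) a reference time in seconds
    resolved to the nearest scan — typically an alignment event such as the
    target cue.  The reference row is exactly zero.
    """
    if isinstance(ref, (int, np.integer)):
        idx = int(ref)
        if not -stream.n_scans <= idx < stream.n_scans:
            raise ValueError(f"reference index {idx} outside stream")
    else:
        if not stream.scan_times[0] <= ref <= stream.scan_times[-1]:
            raise ValueError(f"reference time {ref} outside stream")
        idx = int(np.argmin(np.abs(stream.scan_times - ref)))
    return stream.frames - stream.frames[idx]


def fit_standards(
    training_cvs: np.ndarray,
    labels: list[str],
    concentrations: np.ndarray,
    variance_target: float = 0.99,
    q_percentile: float = 95.0,
) -> StandardsLibrary:
    """Fit the PC subspace and dopamine calibration from labelled standards.

    ``training_cvs`` are background-subtracted CVs (rows), each labelled
    ``"DA"``, ``"pH"`` or ``"movement"``; ``concentrations`` holds the known
    dopamine concentration (nM) for DA rows (ignored elsewhere).

    Components are computed per analyte class (uncentered SVD — the
    chemometric convention for background-subtracted CVs, so a zero ΔI frame
    projects to zero scores and zero residual), retained up to
    ``variance_target`` of each class's variance, and merged into one
    orthonormal subspace.  Per-class retention guarantees every analyte
    direction is represented even when class magnitudes differ widely
    (movement artifacts dwarf dopamine currents).  The calibration regresses
    known DA concentration on the scores over all standards, through the
    origin; pH and movement rows enter at 0 nM, which orthogonalises the
    dopamine readout against their score directions.  Q_alpha is the
    ``q_percentile`` of leave-one-out training residuals — each standard is
    projected onto the subspace built without it, so the tolerance reflects
    out-of-sample measurement noise rather than in-sample fit (with a small
    positive floor so exactly-spanned training sets keep a valid tolerance).
    """
    X = np.atleast_2d(np.asarray(training_cvs, dtype=float))
    labels = list(labels)
    conc = np.asarray(concentrations, dtype=float)
    if X.shape[0] != len(labels) or conc.size != len(labels):
        raise ValueError("training rows, labels and concentrations must align")
    for cls in ("DA", "pH", "movement"):
        if labels.count(cls) < 2:
            raise ValueError(f"need >= 2 training CVs of class {cls!r}")
    if not (X**2).sum():
        raise ValueError("degenerate training set: zero variance")
    lab_arr = np.asarray(labels)
    comps = _union_subspace(X, lab_arr, variance_target)
    scores = X @ comps.T
    # dopamine calibration: regress known [DA] on scores over *all* standards,
    # through the origin; interferent rows (pH, movement) enter at 0 nM, which
    # orthogonalises the readout against their score directions
    y = np.where(np.asarray(labels) == "DA", conc, 0.0)
    coef, *_ = np.linalg.lstsq(scores, y, rcond=None)
    # leave-one-out residuals: each row against the subspace built without it
    q_loo = np.empty(X.shape[0])
    for i in range(X.shape[0]):
        keep = np.ones(X.shape[0], dtype=bool)
        keep[i] = False
        comps_i = _union_subspace(X[keep], lab_arr[keep], variance_target)
        resid_i = X[i] - (X[i] @ comps_i.T) @ comps_i
        q_loo[i] = (resid_i**2).sum()
    floor = 1e-9 * float((X**2).sum(axis=1).mean()) + 1e-12
    q_alpha = max(float(np.percentile(q_loo, q_percentile)), floor)
    mov = X[[i for i, l in enumerate(labels) if l == "movement"]]
    return StandardsLibrary(
        components=comps, coef=coef, q_alpha=q_alpha, movement_templates=mov
    )


def _union_subspace(
    X: np.ndarray, labels: np.ndarray, variance_target: float
) -> np.ndarray:
    """Orthonormal union of per-class principal subspaces (uncentered)."""
    basis_rows = []
    for cls in np.unique(labels):
        Xc = X[labels == cls]
        _, s, Vt = np.linalg.svd(Xc, full_matrices=False)
        var = s**2
        if var.sum() == 0:
            continue
        frac = np.cumsum(var) / var.sum()
        k = int(np.searchsorted(frac, variance_target) + 1)
        k = min(k, int((s > s[0] * 1e-10).sum()))
        basis_rows.append(Vt[:k])
    stacked = np.vstack(basis_rows)
    _, s_all, Vt_all = np.linalg.svd(stacked, full_matrices=False)
    return Vt_all[s_all > 1e-10]


def _pearson_rows(delta_i: np.ndarray, templates: np.ndarray) -> np.ndarray:
    """Max Pearson r of each ΔI row against any movement template."""
    a = delta_i - delta_i.mean(axis=1, keepdims=True)
    b = templates - templates.mean(axis=1, keepdims=True)
    an = np.linalg.norm(a, axis=1)
    bn = np.linalg.norm(b, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (a @ b.T) / np.outer(an, bn)
    r = np.nan_to_num(r, nan=0.0)
    return r.max(axis=1) if templates.size else np.zeros(delta_i.shape[0])


def project(
    delta_i: np.ndarray,
    lib: StandardsLibrary,
    scan_times: np.ndarray | None = None,
    movement_r_threshold: float = 0.8,
) -> DATrace:
    """Project ΔI onto the standards subspace and read out [ΔDA].

    Per scan: PC scores → ΔDA via the calibration regression; Q is the
    squared residual norm outside the subspace.  Scans with Q > Q_alpha are
    nulled (reason ``Q_exceeded``); scans correlating with any movement
    template at r > ``movement_r_threshold`` are nulled (reason
    ``movement_corr``, which takes precedence).  Nulled scans carry NaN.
    """
    D = np.atleast_2d(np.asarray(delta_i, dtype=float))
    if D.shape[1] != lib.components.shape[1]:
        raise ValueError("ΔI point count does not match standards library")
    if scan_times is None:
        scan_times = np.arange(D.shape[0]) * 0.1
    scores = D @ lib.components.T
    da = scores @ lib.coef
    resid = D - scores @ lib.components
    q = (resid**2).sum(axis=1)
    r_mov = _pearson_rows(D, lib.movement_templates)
    reasons: list[str] = []
    out = da.astype(float)
    for i in range(D.shape[0]):
        if r_mov[i] > movement_r_threshold and np.abs(D[i]).max() > 0:
            reasons.append(NULL_MOVEMENT)
            out[i] = np.nan
        elif q[i] > lib.q_alpha:
            reasons.append(NULL_Q)
            out[i] = np.nan
        else:
            reasons.append(NULL_NONE)
    return DATrace(
        times=np.asarray(scan_times, dtype=float),
        delta_da=out, q_values=q, null_reason=reasons,
    )


def color_plot_matrix(delta_i: np.ndarray, stream: CVStream) -> np.ndarray:
    """Background-subtracted current as a (voltage x time) matrix for the
    standard FSCV color plot (scan voltage on y, scan time on x).  Pure
    reshaping: column j equals scan j's ΔI vector."""
    D = np.atleast_2d(np.asarray(delta_i, dtype=float))
    if D.shape != stream.frames.shape:
        raise ValueError("ΔI shape must match the stream")
    return D.T.copy()
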