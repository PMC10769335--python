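"""Peri-event alignment and condition-split trial averaging.

The behavioural task: the subject fixates a central start cue (C), a
peripheral target (T) appears left or right, and after a 4 s fixation a small
or large liquid reward (RW) is delivered.  The direction↔reward-size mapping
switches every 20–30 trials.  This module generates synthetic trial tables,
aligns spike trains or [ΔDA] traces to task events, and computes per-condition
trial averages (mean ± SE) with explicit missing-value handling for nulled
dopamine scans.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

EVENT_COLUMNS = ("C_time", "T_time", "RW_time")


@dataclass
class TrialTable:
    """Behavioural events per trial with reward-size / direction attributes."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        required = set(EVENT_COLUMNS) | {"reward_size", "target_dir", "block"}
        missing = required - set(self.df.columns)
        if missing:
            raise ValueError(f"TrialTable missing columns: {sorted(missing)}")
        bad = self.df.index[
            ~(
                (self.df.C_time < self.df.T_time)
                & (self.df.T_time < self.df.RW_time)
            )
        ].tolist()
        if bad:
            raise ValueError(f"within-trial event order violated at trials {bad}")

    def __len__(self) -> int:
        return len(self.df)

    def event_times(self, event: str) -> np.ndarray:
        col = event if event in self.df.columns else f"{event}_time"
        return self.df[col].to_numpy(dtype=float)

    def condition(self, split_by: str) -> np.ndarray:
        return self.df[split_by].to_numpy()


@dataclass
class AlignedMatrix:
    """Trials x time-bins matrix (spike rate in Hz, or [ΔDA] in nM)."""

    data: np.ndarray  # NaN marks missing (nulled) bins
    bin_centers: np.ndarray  # s relative to the alignment event
    event: str
    conditions: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]


def gen_trials(
    n_trials: int,
    seed: int = 0,
    start_s: float = 5.0,
    iti_s: tuple[float, float] = (2.0, 4.0),
    c_to_t_s: float = 1.6,
    t_to_rw_s: float = 4.0,
    block_range: tuple[int, int] = (20, 30),
) -> TrialTable:
    """Synthetic trial table with block-switched direction↔size mapping.

    C→T latency defaults to the 1.6 s central fixation; T→RW is the 4 s
    peripheral fixation before reward.  Target direction is random per trial;
    reward size follows the block's mapping, which flips every 20–30 trials
    (uniform).
    """
    rng = np.random.default_rng(seed)
    rows = []
    t = start_s
    block, left_in_block = 0, int(rng.integers(block_range[0], block_range[1] + 1))
    mapping = {"left": "large", "right": "small"}
    for _ in range(n_trials):
        if left_in_block == 0:
            block += 1
            left_in_block = int(rng.integers(block_range[0], block_range[1] + 1))
            mapping = {d: ("small" if s == "large" else "large") for d, s in mapping.items()}
        direction = "left" if rng.random() < 0.5 else "right"
        c = t
        rows.append(
            {
                "C_time": c,
                "T_time": c + c_to_t_s,
                "RW_time": c + c_to_t_s + t_to_rw_s,
                "reward_size": mapping[direction],
                "target_dir": direction,
                "block": block,
            }
        )
        t = c + c_to_t_s + t_to_rw_s + rng.uniform(*iti_s)
        left_in_block -= 1
    df = pd.DataFrame(
        rows, columns=list(EVENT_COLUMNS) + ["reward_size", "target_dir", "block"]
    )
    return TrialTable(df)


def align(
    data,
    events: np.ndarray,
    window: tuple[float, float] = (-2.0, 6.0),
    bin_s: float = 0.05,
    data_times: np.ndarray | None = None,
    event_name: str = "",
    span: tuple[float, float] | None = None,
) -> AlignedMatrix:
    """Align spikes or a sampled trace to events, one row per trial.

    ``data`` is either a 1-D array of spike times (binned counts / bin width,
    giving Hz) or, with ``data_times`` supplied, a sampled trace such as
    [ΔDA] whose values are averaged within each bin (NaN samples — nulled
    scans — propagate as missing, never as zero).  Trials whose window
    exceeds the data span are dropped with a warning.
    """
    events = np.asarray(events, dtype=float)
    if events.size == 0:
        raise ValueError("no alignment events")
    lo, hi = window
    edges = np.arange(lo, hi + bin_s / 2, bin_s)
    centers = (edges[:-1] + edges[1:]) / 2
    is_trace = data_times is not None
    if is_trace:
        data_times = np.asarray(data_times, dtype=float)
        values = np.asarray(data, dtype=float)
        span = span or (data_times[0], data_times[-1])
    else:
        times = np.asarray(data, dtype=float)
        span = span or (
            min(times[0], events[0]) if times.size else events[0],
            max(times[-1], events[-1]) if times.size else events[-1],
        )
    keep = (events + lo >= span[0]) & (events + hi <= span[1])
    if not keep.all():
        import warnings

        warnings.warn(f"{int((~keep).sum())} edge trial(s) dropped")
    events = events[keep]
    out = np.full((events.size, centers.size), np.nan)
    for i, ev in enumerate(events):
        if is_trace:
            rel = data_times - ev
            idx = np.digitize(rel, edges) - 1
            ok = (idx >= 0) & (idx < centers.size)
            for b in range(centers.size):
                vals = values[ok & (idx == b)]
                vals = vals[np.isfinite(vals)]
                if vals.size:
                    out[i, b] = vals.mean()
        else:
            counts, _ = np.histogram(times - ev, bins=edges)
            out[i] = counts / bin_s
    mat = AlignedMatrix(data=out, bin_centers=centers, event=event_name)
    mat._kept = keep  # trial mask, for attaching condition labels
    return mat


def attach_conditions(mat: AlignedMatrix, trials: TrialTable) -> AlignedMatrix:
    """Attach reward-size / target-direction labels for the kept trials."""
    kept = getattr(mat, "_kept", np.ones(len(trials), dtype=bool))
    for col in ("reward_size", "target_dir"):
        mat.conditions[col] = trials.condition(col)[kept]
    return mat


def condition_average(
    mat: AlignedMatrix, split_by: str
) -> dict[str, dict[str, np.ndarray | int]]:
    """Across-trial mean ± SE per condition, per time bin.

    Missing (NaN) bins are excluded from the mean's denominator.  Conditions
    with fewer than 2 trials are excluded with a warning.
    """
    if split_by not in mat.conditions:
        raise ValueError(f"no condition labels {split_by!r} attached")
    labels = mat.conditions[split_by]
    out: dict[str, dict[str, np.ndarray | int]] = {}
    for cond in np.unique(labels):
        rows = mat.data[labels == cond]
        if rows.shape[0] < 2:
            import warnings

            warnings.warn(f"condition {cond!r} has < 2 trials; excluded")
            continue
        n_eff = np.isfinite(rows).sum(axis=0)
        with np.errstate(invalid="ignore"):
            mean = np.nanmean(rows, axis=0)
            sd = np.nanstd(rows, axis=0, ddof=1)
        se = np.where(n_eff > 1, sd / np.sqrt(np.maximum(n_eff, 1)), np.nan)
        out[str(cond)] = {"mean": mean, "se": se, "n_trials": rows.shape[0]}
    return out


def permutation_test(
    mat: AlignedMatrix,
    split_by: str,
    window: tuple[float, float],
    n_perm: int = 1000,
    seed: int = 0,
) -> float:
    """Two-sided permutation p-value for a condition difference in window
    means (the across-bin mean within ``window``, compared between the two
    condition groups by shuffling labels)."""
    labels = mat.conditions[split_by]
    uniq = np.unique(labels)
    if uniq.size != 2:
        raise ValueError("permutation test requires exactly 2 conditions")
    sel = (mat.bin_centers >= window[0]) & (mat.bin_centers < window[1])
    per_trial = np.nanmean(mat.data[:, sel], axis=1)
    ok = np.isfinite(per_trial)
    per_trial, labels = per_trial[ok], labels[ok]
    obs = abs(
        per_trial[labels == uniq[0]].mean() - per_trial[labels == uniq[1]].mean()
    )
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(labels)
        d = abs(
            per_trial[perm == uniq[0]].mean() - per_trial[perm == uniq[1]].mean()
        )
        if d >= obs:
            count += 1
    return (count + 1) / (n_perm + 1)
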