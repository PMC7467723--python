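"""Molecular quantifications: comparative ΔΔCt, poly(A)-tail gel densitometry,
and immunoblot band ratios.

``delta_delta_ct`` implements the comparative Ct method for qPCR: per group,
the target gene's mean Ct is normalized to a reference gene (ΔCt), the
control group's ΔCt is subtracted (ΔΔCt), and fold change is 2**(-ΔΔCt).
Two replicate-handling conventions are supported; both rescale so the
control group is exactly 1.

``LaneProfile`` / ``average_and_find_peaks`` handle PAT-PCR readouts: a gel
lane's intensity profile indexed by estimated poly(A) tail length is
background-subtracted and max-normalized, replicate lanes are averaged, and
the poly(A) length distribution is summarized by its primary (global) and
secondary (local) intensity maxima.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

__all__ = [
    "CtTable",
    "LaneProfile",
    "PeakCall",
    "delta_delta_ct",
    "normalize_profile",
    "average_and_find_peaks",
    "band_ratio",
]

_CT_COLUMNS = ("sample_group", "gene", "replicate", "ct")


def CtTable(rows) -> pd.DataFrame:
    """Validate a qPCR Ct table (columns sample_group, gene, replicate, ct)."""
    df = pd.DataFrame(rows)
    missing = set(_CT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"Ct table missing columns: {sorted(missing)}")
    if (df["ct"] <= 0).any():
        raise ValueError("Ct values must be positive cycle numbers")
    return df


def delta_delta_ct(
    table: pd.DataFrame,
    target: str,
    reference: str,
    control_group: str,
    mode: str = "average_folds",
) -> pd.Series:
    """Relative abundance of ``target`` per sample group by the comparative
    ΔΔCt method, normalized to ``reference`` and scaled so that
    ``control_group`` is exactly 1.

    mode="mean_ct" (classic): ΔCt = mean Ct(target) − mean Ct(reference) per
    group; ΔΔCt = ΔCt − ΔCt(control); fold = 2**(−ΔΔCt).

    mode="average_folds": a fold change is computed per replicate (pairing
    target and reference replicates within the group), replicate folds are
    averaged per group, and group averages are rescaled to the control
    group's average.  With a single replicate per group the two modes agree.
    """
    groups = table["sample_group"].unique().tolist()
    if control_group not in groups:
        raise ValueError(f"control group {control_group!r} not in table")
    for gene in (target, reference):
        for g in groups:
            sub = table[(table["sample_group"] == g) & (table["gene"] == gene)]
            if sub.empty:
                raise ValueError(f"gene {gene!r} missing in group {g!r}")

    tgt = table[table["gene"] == target]
    ref = table[table["gene"] == reference]

    if mode == "mean_ct":
        d_ct = (
            tgt.groupby("sample_group")["ct"].mean()
            - ref.groupby("sample_group")["ct"].mean()
        )
        dd_ct = d_ct - d_ct[control_group]
        fold = 2.0 ** (-dd_ct)
    elif mode == "average_folds":
        merged = tgt.merge(
            ref,
            on=["sample_group", "replicate"],
            suffixes=("_target", "_reference"),
        )
        if merged.empty:
            raise ValueError(
                "average_folds mode requires matching replicate ids for "
                "target and reference genes"
            )
        merged["rel"] = 2.0 ** (-(merged["ct_target"] - merged["ct_reference"]))
        per_group = merged.groupby("sample_group")["rel"].mean()
        fold = per_group / per_group[control_group]
    else:
        raise ValueError("mode must be 'mean_ct' or 'average_folds'")
    fold.name = "fold_change"
    return fold.reindex(groups)


@dataclass(frozen=True)
class LaneProfile:
    """One gel lane: intensity versus estimated poly(A) tail length (nt).

    The tail-length axis comes from the caller's size calibration and must
    be monotone increasing.  ``background`` is the scalar subtracted during
    normalization.
    """

    tail_length_nt: np.ndarray
    intensity: np.ndarray
    background: float = 0.0
    normalized: bool = False

    def __post_init__(self) -> None:
        axis = np.asarray(self.tail_length_nt, dtype=float)
        inten = np.asarray(self.intensity, dtype=float)
        if axis.size != inten.size:
            raise ValueError("axis and intensity must have equal length")
        if axis.size < 2 or (np.diff(axis) <= 0).any():
            raise ValueError("tail-length axis must be monotone increasing")
        if not np.isfinite(inten).all():
            raise ValueError("intensities must be finite")
        if (inten < 0).any():
            raise ValueError("intensities must be non-negative")
        object.__setattr__(self, "tail_length_nt", axis)
        object.__setattr__(self, "intensity", inten)


def normalize_profile(profile: LaneProfile) -> LaneProfile:
    """Background-subtract, clip at zero, and scale to unit maximum."""
    if profile.normalized:
        return profile
    sub = np.clip(profile.intensity - profile.background, 0.0, None)
    peak = sub.max()
    if peak <= 0:
        raise ValueError("profile is zero everywhere after background subtraction")
    return replace(profile, intensity=sub / peak, normalized=True)


@dataclass(frozen=True)
class PeakCall:
    """Primary and secondary poly(A) peak locations (nt)."""

    primary_nt: float
    secondary_nt: tuple[float, ...]
    mean_profile: LaneProfile
    tie: bool = False


def average_and_find_peaks(
    profiles: Sequence[LaneProfile],
    secondary_fraction: float = 0.5,
    min_separation_steps: int = 3,
) -> PeakCall:
    """Average normalized replicate lanes and locate intensity maxima.

    The primary peak is the global maximum of the mean profile (ties resolve
    to the smallest tail length and set the ``tie`` flag).  Secondary peaks
    are local maxima at least ``secondary_fraction`` of the primary height,
    separated from it and from each other by at least
    ``min_separation_steps`` axis steps.
    """
    if not profiles:
        raise ValueError("need at least one profile")
    profiles = [normalize_profile(p) for p in profiles]
    axis = profiles[0].tail_length_nt
    for p in profiles[1:]:
        if p.tail_length_nt.size != axis.size or not np.allclose(p.tail_length_nt, axis):
            raise ValueError("profiles must share a common tail-length axis")
    mean = np.mean([p.intensity for p in profiles], axis=0)

    primary_idx = int(np.argmax(mean))  # argmax returns the first (smallest nt) tie
    tie = bool(np.sum(np.isclose(mean, mean[primary_idx])) > 1)
    primary_height = mean[primary_idx]

    idx, _ = find_peaks(
        mean,
        height=secondary_fraction * primary_height,
        distance=max(1, min_separation_steps),
    )
    secondary = tuple(
        float(axis[i])
        for i in idx
        if abs(i - primary_idx) >= min_separation_steps
    )
    mean_profile = LaneProfile(axis, mean, background=0.0, normalized=True)
    return PeakCall(
        primary_nt=float(axis[primary_idx]),
        secondary_nt=secondary,
        mean_profile=mean_profile,
        tie=tie,
    )


def band_ratio(
    target_band: float,
    loading_band: float,
    control_target: float,
    control_loading: float,
) -> float:
    """Immunoblot fold change: (target/loading) / (control_target/control_loading).

    The loading-control band (e.g. α-tubulin) normalizes lane-to-lane loading.
    """
    if loading_band <= 0 or control_loading <= 0:
        raise ValueError("loading-control intensities must be positive")
    return (target_band / loading_band) / (control_target / control_loading)
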