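"""Metacarpophalangeal pattern-profile analysis.

Hand-bone lengths from roentgenograms are standardized against age- and
sex-specific reference norms: z = (length − mean) / SD.  The 19 bones of
one hand (five metacarpals, five proximal, four middle and five distal
phalanges — the thumb has no middle phalanx) form a pattern profile per
(individual, side).  Profiles of affected and unaffected siblings are
compared as group means; a group-mean deficit beyond a configurable
threshold operationalizes brachydactyly, and individual bones far below
expectation are flagged as markedly shortened.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: Fixed bone vocabulary: metacarpals 1-5, proximal phalanges 1-5,
#: middle phalanges 2-5, distal phalanges 1-5.
HAND_BONES = (
    "MC1", "MC2", "MC3", "MC4", "MC5",
    "PP1", "PP2", "PP3", "PP4", "PP5",
    "MP2", "MP3", "MP4", "MP5",
    "DP1", "DP2", "DP3", "DP4", "DP5",
)


class NormTable:
    """Reference moments per (bone, sex, age): mean and SD of length in mm."""

    COLUMNS = ("bone_id", "sex", "age_years", "mean_mm", "sd_mm")

    def __init__(self, frame: pd.DataFrame):
        missing = set(self.COLUMNS) - set(frame.columns)
        if missing:
            raise ValueError(f"norm table missing columns {sorted(missing)}")
        if (frame["sd_mm"] <= 0).any():
            raise ValueError("norm table has non-positive SDs")
        frame = frame.sort_values(["bone_id", "sex", "age_years"]).reset_index(
            drop=True
        )
        for (bone, sex), grp in frame.groupby(["bone_id", "sex"]):
            ages = grp["age_years"].to_numpy()
            if not np.all(np.diff(ages) > 0):
                raise ValueError(
                    f"ages not strictly increasing for bone {bone} sex {sex}"
                )
        self.frame = frame

    def write_tsv(self, path: str | Path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path: str | Path) -> "NormTable":
        return cls(pd.read_csv(path, sep="\t"))


def z_score(length_mm: float, mean_mm: float, sd_mm: float) -> float:
    """Standardized bone length in SD units."""
    if sd_mm <= 0:
        raise ValueError("sd_mm must be positive")
    return (length_mm - mean_mm) / sd_mm


def lookup_norm(
    norms: NormTable, bone: str, sex: int, age_years: float
) -> tuple[float, float]:
    """Reference (mean, SD) for a bone at a given sex and age.

    Exact tabulated ages are returned as-is; ages between two tabulated
    rows are linearly interpolated; ages outside the tabulated range are
    an error (no extrapolation).
    """
    grp = norms.frame[
        (norms.frame["bone_id"] == bone) & (norms.frame["sex"] == sex)
    ]
    if grp.empty:
        raise KeyError(f"no norms for bone {bone!r} sex {sex}")
    ages = grp["age_years"].to_numpy()
    if age_years < ages[0] or age_years > ages[-1]:
        raise ValueError(
            f"age {age_years} outside tabulated range "
            f"[{ages[0]}, {ages[-1]}] for bone {bone!r}"
        )
    mean = float(np.interp(age_years, ages, grp["mean_mm"].to_numpy()))
    sd = float(np.interp(age_years, ages, grp["sd_mm"].to_numpy()))
    return mean, sd


@dataclass
class ZProfile:
    """One hand's standardized bone lengths."""

    individual: str
    side: str
    z: dict[str, float] = field(default_factory=dict)

    def mean(self) -> float:
        return float(np.mean(list(self.z.values())))


def profile_hands(
    measurements: pd.DataFrame,
    norms: NormTable,
    persons: pd.DataFrame,
) -> list[ZProfile]:
    """Pattern profiles for every (individual, side) in ``measurements``.

    ``measurements`` columns: individual, side, bone_id, length_mm.
    ``persons`` columns: individual, sex, age_years (affection optional);
    it supplies the age/sex lookup into the norms.
    """
    demo = persons.set_index("individual")
    profiles: list[ZProfile] = []
    for (iid, side), grp in measurements.groupby(
        ["individual", "side"], sort=False
    ):
        if iid not in demo.index:
            raise KeyError(f"individual {iid!r} missing from persons table")
        sex = int(demo.loc[iid, "sex"])
        age = float(demo.loc[iid, "age_years"])
        prof = ZProfile(individual=str(iid), side=str(side))
        for row in grp.itertuples(index=False):
            mean, sd = lookup_norm(norms, row.bone_id, sex, age)
            prof.z[row.bone_id] = z_score(row.length_mm, mean, sd)
        profiles.append(prof)
    return profiles


def profiles_frame(profiles: Iterable[ZProfile]) -> pd.DataFrame:
    rows = [
        {"individual": p.individual, "side": p.side, "bone_id": b, "z": z}
        for p in profiles
        for b, z in p.z.items()
    ]
    return pd.DataFrame(rows, columns=["individual", "side", "bone_id", "z"])


@dataclass
class ProfileComparison:
    mean_z_affected: float
    mean_z_unaffected: float
    difference: float  # affected − unaffected
    brachydactyly: bool
    marked_bones: list[tuple[str, str, str, float]]  # individual, side, bone, z

    def to_dict(self) -> dict:
        return {
            "mean_z_affected": self.mean_z_affected,
            "mean_z_unaffected": self.mean_z_unaffected,
            "difference": self.difference,
            "brachydactyly": self.brachydactyly,
            "marked_bones": [list(m) for m in self.marked_bones],
        }


def compare_profiles(
    affected_profiles: Sequence[ZProfile],
    unaffected_profiles: Sequence[ZProfile],
    brachydactyly_delta: float = 1.0,
    marked_threshold: float = -5.0,
) -> ProfileComparison:
    """Group-level comparison of affected vs unaffected pattern profiles.

    The brachydactyly flag fires when the affected group's mean z across
    all bones and sides sits at least ``brachydactyly_delta`` SD below the
    unaffected group's.  Any single bone with z ≤ ``marked_threshold``
    (either group) is reported as markedly shortened.
    """
    if not affected_profiles or not unaffected_profiles:
        raise ValueError("need at least one profile per group")
    z_aff = [z for p in affected_profiles for z in p.z.values()]
    z_un = [z for p in unaffected_profiles for z in p.z.values()]
    mean_aff = float(np.mean(z_aff))
    mean_un = float(np.mean(z_un))
    diff = mean_aff - mean_un
    marked = [
        (p.individual, p.side, bone, z)
        for p in [*affected_profiles, *unaffected_profiles]
        for bone, z in p.z.items()
        if z <= marked_threshold
    ]
    return ProfileComparison(
        mean_z_affected=mean_aff,
        mean_z_unaffected=mean_un,
        difference=diff,
        brachydactyly=diff <= -brachydactyly_delta,
        marked_bones=marked,
    )


def plot_profiles(
    profiles: Sequence[ZProfile], path: str | Path, title: str = ""
) -> None:
    """Line plot of pattern profiles (one line per individual/side)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(10, 4))
    x = np.arange(len(HAND_BONES))
    for p in profiles:
        y = [p.z.get(b, np.nan) for b in HAND_BONES]
        ax.plot(x, y, marker="o", label=f"{p.individual} ({p.side})")
    ax.axhline(1.0, color="red", lw=0.8, ls="--")
    ax.axhline(-1.0, color="red", lw=0.8, ls="--")
    ax.set_xticks(x)
    ax.set_xticklabels(HAND_BONES, rotation=60)
    ax.set_ylabel("z (SD units)")
    if title:
        ax.set_title(title)
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
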