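"""Facial anthropometrics and their association with goodness of fit.

Four landmark-pair distances commonly used in respirator-fit research:
bio-ocular width (outer eye corner to outer eye corner), alar width
(nostril flank to nostril flank), dorsal nasal length (nasion to nose
tip) and lower-third facial height (subnasale to menton). Associations
with GoF percentages are assessed with Shapiro-Wilk normality checks and
Pearson correlation at the 5% significance level.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "LandmarkSet",
    "AnthropometricProfile",
    "CorrelationResult",
    "MissingLandmarkError",
    "load_landmarks",
    "measure_profile",
    "association",
]

REQUIRED_LANDMARKS = (
    "exocanthion_left",
    "exocanthion_right",
    "alare_left",
    "alare_right",
    "nasion",
    "pronasale",
    "subnasale",
    "menton",
)

#: Accepted alternative landmark names (anatomical synonyms).
LANDMARK_ALIASES = {
    "sellion": "nasion",
    "stomion": "menton",  # lower-third surrogate when the chin is cut off
}


class MissingLandmarkError(KeyError):
    """A required landmark is absent from the set."""


@dataclass
class LandmarkSet:
    """Named 3D facial landmarks in mm."""

    points: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        cleaned: dict[str, np.ndarray] = {}
        for name, p in self.points.items():
            name = LANDMARK_ALIASES.get(name, name)
            p = np.asarray(p, dtype=np.float64).reshape(3)
            if not np.isfinite(p).all():
                raise ValueError(f"landmark {name!r} has non-finite coordinates")
            cleaned[name] = p
        self.points = cleaned

    def __getitem__(self, name: str) -> np.ndarray:
        name = LANDMARK_ALIASES.get(name, name)
        if name not in self.points:
            raise MissingLandmarkError(f"missing landmark {name!r}")
        return self.points[name]

    def __contains__(self, name: str) -> bool:
        return LANDMARK_ALIASES.get(name, name) in self.points

    def transformed(self, T) -> "LandmarkSet":
        return LandmarkSet({k: T.apply(v) for k, v in self.points.items()})

    def to_json(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            json.dump({k: v.tolist() for k, v in self.points.items()}, fh, indent=1)


def load_landmarks(path: str | os.PathLike) -> LandmarkSet:
    """Load a landmark file: JSON mapping name -> [x, y, z] in mm, or a
    CSV with columns name, x, y, z."""
    path = os.fspath(path)
    if path.endswith(".json"):
        with open(path) as fh:
            data = json.load(fh)
        return LandmarkSet({k: np.asarray(v) for k, v in data.items()})
    import pandas as pd

    df = pd.read_csv(path)
    return LandmarkSet(
        {
            str(row["name"]): np.array([row["x"], row["y"], row["z"]])
            for _, row in df.iterrows()
        }
    )


@dataclass(frozen=True)
class AnthropometricProfile:
    """The four landmark distances, in mm."""

    lower_third_face_height: float
    alar_width: float
    bio_ocular_width: float
    dorsal_nasal_length: float

    def __post_init__(self) -> None:
        for name, value in self.as_dict().items():
            if not value > 0:
                raise ValueError(
                    f"{name} must be positive, got {value} "
                    "(coincident landmark pair?)"
                )

    def as_dict(self) -> dict[str, float]:
        return {
            "lower_third_face_height": self.lower_third_face_height,
            "alar_width": self.alar_width,
            "bio_ocular_width": self.bio_ocular_width,
            "dorsal_nasal_length": self.dorsal_nasal_length,
        }


def _dist(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.linalg.norm(a - b))


def measure_profile(landmarks: LandmarkSet) -> AnthropometricProfile:
    """Euclidean landmark-pair distances.

    bio-ocular = exocanthion-exocanthion; alar = alare-alare; dorsal
    nasal = nasion-pronasale; lower-third height = subnasale-menton (the
    lower third is used because facial scans routinely cut off the
    hairline, precluding total facial height).
    """
    return AnthropometricProfile(
        lower_third_face_height=_dist(
            landmarks["subnasale"], landmarks["menton"]
        ),
        alar_width=_dist(landmarks["alare_left"], landmarks["alare_right"]),
        bio_ocular_width=_dist(
            landmarks["exocanthion_left"], landmarks["exocanthion_right"]
        ),
        dorsal_nasal_length=_dist(landmarks["nasion"], landmarks["pronasale"]),
    )


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p_value: float
    n: int
    normality_p: float
    significant: bool

    def as_dict(self) -> dict:
        return {
            "r": self.r,
            "p_value": self.p_value,
            "n": self.n,
            "normality_p": self.normality_p,
            "significant": self.significant,
        }


def association(
    gof_values, measurements, alpha: float = 0.05
) -> CorrelationResult:
    """Pearson correlation between a GoF percentage and an anthropometric.

    Both variables are first checked for normality (Shapiro-Wilk;
    ``normality_p`` reports the smaller of the two p-values).
    Significance is a two-sided Pearson test at ``alpha``.
    """
    x = np.asarray(gof_values, dtype=np.float64)
    y = np.asarray(measurements, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("inputs must be equal-length 1D sequences")
    if len(x) < 3:
        raise ValueError("need at least 3 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in an input: correlation undefined")
    shapiro_x = stats.shapiro(x).pvalue
    shapiro_y = stats.shapiro(y).pvalue
    r, p = stats.pearsonr(x, y)
    return CorrelationResult(
        r=float(r),
        p_value=float(p),
        n=len(x),
        normality_p=float(min(shapiro_x, shapiro_y)),
        significant=bool(p <= alpha),
    )
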