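"""Study configuration and shared error types.

The configuration bundles every tunable of the pipeline: intensity
discretization policy, the texture neighbourhood distance, the RBF-SVM
hyperparameters, the cross-validation protocol, the size of the selected
feature set and the Bonferroni family size. Exactly one discretization
policy (fixed bin count or fixed bin width in ppm) is active at a time.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Optional

import yaml


class QsmRadiomicsError(Exception):
    """Base class for package errors."""


class ShapeMismatchError(QsmRadiomicsError):
    """Volume and mask grids disagree in dimensions or affine."""


class DegenerateVoiError(QsmRadiomicsError):
    """The VOI mask is empty or otherwise unusable."""


class IncompleteTableError(QsmRadiomicsError):
    """A feature table does not carry the full canonical feature roster."""


class CohortSpecError(QsmRadiomicsError):
    """A synthetic cohort specification violates its invariants."""


@dataclasses.dataclass
class StudyConfig:
    """Pipeline-wide parameter set.

    Parameters
    ----------
    bin_count:
        Number of gray levels for fixed-bin-count discretization over the
        VOI's own intensity range. Mutually exclusive with ``bin_width``.
    bin_width:
        Bin width in ppm for fixed-bin-width discretization, or ``None``.
    delta:
        Texture neighbourhood distance in voxel steps (>= 1).
    svm_c, svm_gamma:
        RBF-SVM penalty and kernel width.
    cv_folds, cv_repetitions:
        k of the k-fold partition and number of repetitions.
    n_select:
        Number of features kept by the ensemble selector.
    bonferroni_n:
        Family size of the multiple-comparison correction.
    seed:
        Root seed; every stochastic stage derives its stream from it.
    stratified:
        Whether CV folds are stratified by class label.
    leakage_safe_selection:
        If True, feature selection is refit inside each training fold
        instead of once on the full sample.
    paper_mode:
        If True, standardization and PCA are fitted on the full sample
        before cross-validation rather than within each training fold.
    """

    bin_count: Optional[int] = 16
    bin_width: Optional[float] = None
    delta: int = 1
    svm_c: float = 30.0
    svm_gamma: float = 0.001
    cv_folds: int = 3
    cv_repetitions: int = 10
    n_select: int = 40
    bonferroni_n: int = 40
    seed: int = 0
    stratified: bool = True
    leakage_safe_selection: bool = False
    paper_mode: bool = False

    def __post_init__(self) -> None:
        if (self.bin_count is None) == (self.bin_width is None):
            raise ValueError("exactly one of bin_count / bin_width must be set")
        if self.bin_count is not None and self.bin_count < 1:
            raise ValueError("bin_count must be >= 1")
        if self.bin_width is not None and self.bin_width <= 0:
            raise ValueError("bin_width must be > 0")
        if int(self.delta) != self.delta or self.delta < 1:
            raise ValueError("delta must be an integer >= 1")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if self.cv_repetitions < 1:
            raise ValueError("cv_repetitions must be >= 1")
        if self.n_select < 1:
            raise ValueError("n_select must be >= 1")
        if self.svm_c <= 0 or self.svm_gamma <= 0:
            raise ValueError("svm_c and svm_gamma must be > 0")
        if self.bonferroni_n < 1:
            raise ValueError("bonferroni_n must be >= 1")

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "StudyConfig":
        """Load a config from YAML or JSON, applying keyword overrides."""
        path = Path(path)
        with open(path) as fh:
            raw = json.load(fh) if path.suffix == ".json" else yaml.safe_load(fh)
        raw = dict(raw or {})
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**raw)

    def to_file(self, path: str | Path) -> None:
        path = Path(path)
        data = dataclasses.asdict(self)
        with open(path, "w") as fh:
            if path.suffix == ".json":
                json.dump(data, fh, indent=2)
            else:
                yaml.safe_dump(data, fh)
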