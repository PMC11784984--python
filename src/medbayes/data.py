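"""Subject-level mediation datasets and design-matrix construction.

A :class:`MediationDataset` holds one exposure column, one outcome column and
a set of named mediators, each with a declared kind (continuous, binary or
categorical).  Categorical mediators are expanded into reference-coded
indicator columns when design matrices are built, so downstream models see
K-1 dummies against a declared reference level.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

INTERCEPT = "Intercept"


def dummy_name(mediator: str, level: object) -> str:
    """Column label of the indicator for ``mediator == level``."""
    return f"{mediator}[{level}]"


@dataclass(frozen=True)
class MediatorSpec:
    """Declared role and type of a candidate mediator.

    Parameters
    ----------
    name : str
        Column name in the data table.
    kind : {"continuous", "binary", "categorical"}
        Measurement type.  Binary mediators are modelled with a logit link,
        categorical ones with a baseline-category multinomial logit.
    levels : sequence, optional
        Category levels (categorical only).  Order fixes the dummy layout.
    reference_level : object, optional
        Baseline category; defaults to the first level.
    forced : bool
        Bypass the screening tests and always include this mediator.
    group : str, optional
        Label joining mediators whose combined indirect effect is of
        interest (e.g. a walkability construct).
    """

    name: str
    kind: str = "continuous"
    levels: Optional[tuple] = None
    reference_level: Optional[object] = None
    forced: bool = False
    group: Optional[str] = None

    def __post_init__(self) -> None:
        if self.kind not in ("continuous", "binary", "categorical"):
            raise ValueError(f"unknown mediator kind {self.kind!r}")
        if self.kind == "categorical":
            if self.levels is None or len(self.levels) < 2:
                raise ValueError(f"categorical mediator {self.name!r} needs >= 2 levels")
            object.__setattr__(self, "levels", tuple(self.levels))
            ref = self.reference_level if self.reference_level is not None else self.levels[0]
            if ref not in self.levels:
                raise ValueError(
                    f"reference level {ref!r} of {self.name!r} not among levels {self.levels}"
                )
            object.__setattr__(self, "reference_level", ref)

    @property
    def nonreference_levels(self) -> List[object]:
        assert self.kind == "categorical"
        return [lv for lv in self.levels if lv != self.reference_level]

    @property
    def dummy_columns(self) -> List[str]:
        """Indicator column labels for the non-reference levels."""
        return [dummy_name(self.name, lv) for lv in self.nonreference_levels]


class MediationDataset:
    """Exposure / outcome / mediator table with declared variable roles."""

    def __init__(
        self,
        frame: pd.DataFrame,
        exposure: str,
        outcome: str,
        mediators: Sequence[MediatorSpec],
        covariates: Sequence[str] = (),
        outcome_kind: str = "continuous",
        dropna: bool = True,
    ) -> None:
        mediators = list(mediators)
        names = [m.name for m in mediators]
        if len(set(names)) != len(names):
            raise ValueError("duplicate mediator names")
        missing = [
            c for c in [exposure, outcome, *names, *covariates] if c not in frame.columns
        ]
        if missing:
            raise ValueError(f"columns not found in data: {missing}")
        if outcome_kind not in ("continuous", "binary"):
            raise ValueError(f"unknown outcome kind {outcome_kind!r}")

        used = [exposure, outcome, *names, *covariates]
        frame = frame.loc[:, used].copy()
        if dropna:
            n_before = len(frame)
            frame = frame.dropna().reset_index(drop=True)
            dropped = n_before - len(frame)
            if dropped:
                logger.info("complete-case deletion dropped %d of %d rows", dropped, n_before)

        self.frame = frame
        self.exposure_name = exposure
        self.outcome_name = outcome
        self.outcome_kind = outcome_kind
        self.mediators: Dict[str, MediatorSpec] = {m.name: m for m in mediators}
        self.covariates = list(covariates)
        self._validate()

    # -- construction -----------------------------------------------------
    @classmethod
    def from_csv(cls, path, exposure: str, outcome: str, mediators, **kwargs) -> "MediationDataset":
        return cls(pd.read_csv(path), exposure, outcome, mediators, **kwargs)

    def _validate(self) -> None:
        x = self.exposure.to_numpy()
        uniq = np.unique(x)
        if set(uniq) <= {0, 1} and len(uniq) <= 2:
            self.exposure_binary = True
        elif np.issubdtype(np.asarray(x).dtype, np.number):
            self.exposure_binary = False
        else:
            raise ValueError("exposure must be numeric (binary 0/1 or continuous)")
        if self.outcome_kind == "binary":
            vals = set(np.unique(self.outcome.to_numpy()))
            if not vals <= {0, 1}:
                raise ValueError("binary outcome must take values in {0, 1}")
        for spec in self.mediators.values():
            col = self.frame[spec.name]
            if spec.kind == "continuous":
                if not np.issubdtype(col.dtype, np.number):
                    raise ValueError(f"continuous mediator {spec.name!r} is not numeric")
            elif spec.kind == "binary":
                if not set(pd.unique(col)) <= {0, 1}:
                    raise ValueError(f"binary mediator {spec.name!r} must be coded 0/1")
            else:
                observed = set(pd.unique(col))
                if not observed <= set(spec.levels):
                    extra = observed - set(spec.levels)
                    raise ValueError(
                        f"categorical mediator {spec.name!r} has undeclared levels {sorted(map(str, extra))}"
                    )

    # -- accessors ---------------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.frame)

    @property
    def exposure(self) -> pd.Series:
        return self.frame[self.exposure_name]

    @property
    def outcome(self) -> pd.Series:
        return self.frame[self.outcome_name]

    def mediator_values(self, name: str) -> pd.Series:
        return self.frame[name]

    @property
    def groups(self) -> Dict[str, List[str]]:
        """Declared mediator groups, group label -> member names."""
        out: Dict[str, List[str]] = {}
        for spec in self.mediators.values():
            if spec.group is not None:
                out.setdefault(spec.group, []).append(spec.name)
        return out

    # -- design matrices ---------------------------------------------------
    def mediator_block(self, name: str) -> pd.DataFrame:
        """Columns a mediator contributes to the outcome design matrix."""
        spec = self.mediators[name]
        col = self.frame[name]
        if spec.kind in ("continuous", "binary"):
            return col.to_frame()
        data = {
            dummy_name(name, lv): (col == lv).astype(float)
            for lv in spec.nonreference_levels
        }
        return pd.DataFrame(data, index=self.frame.index)

    def outcome_design(self, mediator_names: Optional[Iterable[str]] = None) -> pd.DataFrame:
        """Design matrix for the outcome model: intercept, exposure, mediator
        blocks (reference-coded) and extra covariates."""
        if mediator_names is None:
            mediator_names = list(self.mediators)
        parts = [
            pd.Series(1.0, index=self.frame.index, name=INTERCEPT).to_frame(),
            self.exposure.astype(float).to_frame(),
        ]
        for name in mediator_names:
            parts.append(self.mediator_block(name).astype(float))
        for cov in self.covariates:
            parts.append(self.frame[cov].astype(float).to_frame())
        return pd.concat(parts, axis=1)

    def mediator_design(self, extra_covariates: Sequence[str] = ()) -> pd.DataFrame:
        """Design matrix for a mediator model: intercept, exposure and any
        requested extra covariates (exposure-only by default)."""
        parts = [
            pd.Series(1.0, index=self.frame.index, name=INTERCEPT).to_frame(),
            self.exposure.astype(float).to_frame(),
        ]
        for cov in extra_covariates:
            parts.append(self.frame[cov].astype(float).to_frame())
        return pd.concat(parts, axis=1)

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        kinds = {m.name: m.kind for m in self.mediators.values()}
        return (
            f"MediationDataset(n={self.n}, exposure={self.exposure_name!r} "
            f"({'binary' if self.exposure_binary else 'continuous'}), "
            f"outcome={self.outcome_name!r} ({self.outcome_kind}), mediators={kinds})"
        )
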