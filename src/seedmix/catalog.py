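"""Variety catalog and composition vectors.

A seed mix is described by the weight fraction of each variety in a fixed,
ordered catalog.  The canonical catalog holds the 11 cereal/legume varieties
commonly grown in cereal–legume feed mixes (meslin) plus a residual "other"
category for debris (stems, husks, unidentified seeds) that is weighed along
with the grain.  Composition vectors live on the probability simplex: they are
nonnegative and sum to 1, whether they are ground truth from weighing or model
predictions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CANONICAL_VARIETIES",
    "OTHER_LABEL",
    "VarietyCatalog",
    "CompositionVector",
    "CompositionError",
    "validate_composition",
    "renormalize_known",
]

#: Canonical ordering of the 11 main varieties.  Serialized vectors (manifest
#: columns, prediction CSVs) always use this order so runs are comparable.
CANONICAL_VARIETIES: tuple[str, ...] = (
    "triticale",
    "oats",
    "barley",
    "spelt",
    "wheat",
    "rye",
    "forage_peas",
    "faba_bean",
    "vetch",
    "protein_peas",
    "lupine",
)

OTHER_LABEL = "other"


class CompositionError(ValueError):
    """A weight vector violates the simplex constraints."""


@dataclass(frozen=True)
class VarietyCatalog:
    """Ordered set of category labels a composition is expressed over.

    Parameters
    ----------
    names
        Unique, non-empty labels.  If ``includes_other`` is True the residual
        label must be the last entry.
    includes_other
        Whether the final category is the residual "other" class.
    """

    names: tuple[str, ...]
    includes_other: bool = False

    def __post_init__(self) -> None:
        names = tuple(self.names)
        object.__setattr__(self, "names", names)
        if not names:
            raise ValueError("catalog needs at least one label")
        if any(not n for n in names):
            raise ValueError("catalog labels must be non-empty")
        if len(set(names)) != len(names):
            raise ValueError("catalog labels must be unique")
        if self.includes_other and names[-1] != OTHER_LABEL:
            raise ValueError(
                f"residual label {OTHER_LABEL!r} must be last when includes_other is set"
            )

    def __len__(self) -> int:
        return len(self.names)

    def __iter__(self):
        return iter(self.names)

    def index(self, label: str) -> int:
        return self.names.index(label)

    @property
    def known_names(self) -> tuple[str, ...]:
        """Labels excluding the residual category."""
        return self.names[:-1] if self.includes_other else self.names

    def without_other(self) -> "VarietyCatalog":
        if not self.includes_other:
            return self
        return VarietyCatalog(self.names[:-1], includes_other=False)

    @classmethod
    def default(cls, includes_other: bool = True) -> "VarietyCatalog":
        """The 11 canonical varieties, plus "other" unless disabled."""
        if includes_other:
            return cls(CANONICAL_VARIETIES + (OTHER_LABEL,), includes_other=True)
        return cls(CANONICAL_VARIETIES, includes_other=False)


@dataclass(frozen=True)
class CompositionVector:
    """Weight fractions over a catalog, constrained to the simplex."""

    catalog: VarietyCatalog
    weights: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "weights", w)
        w.setflags(write=False)

    def __getitem__(self, label: str) -> float:
        return float(self.weights[self.catalog.index(label)])

    def as_dict(self) -> dict[str, float]:
        return {n: float(v) for n, v in zip(self.catalog.names, self.weights)}

    @property
    def other_weight(self) -> float:
        if not self.catalog.includes_other:
            return 0.0
        return float(self.weights[-1])

    @classmethod
    def from_dict(
        cls,
        values: dict[str, float],
        catalog: VarietyCatalog | None = None,
        tol: float = 1e-6,
    ) -> "CompositionVector":
        """Build and validate from a label -> fraction mapping; missing labels are 0."""
        cat = catalog or VarietyCatalog.default()
        unknown = set(values) - set(cat.names)
        if unknown:
            raise CompositionError(f"labels not in catalog: {sorted(unknown)}")
        w = [values.get(n, 0.0) for n in cat.names]
        return validate_composition(w, cat, tol=tol)


def validate_composition(
    weights,
    catalog: VarietyCatalog,
    tol: float = 1e-6,
) -> CompositionVector:
    """Validate a raw weight vector and renormalize it exactly onto the simplex.

    Accepts vectors whose sum deviates from 1 by at most ``tol`` and divides
    through by the actual sum, so the stored vector sums to 1 exactly (up to
    float rounding).  Negative entries or a larger sum deviation raise
    :class:`CompositionError`.
    """
    w = np.asarray(weights, dtype=float)
    if w.ndim != 1 or w.size != len(catalog):
        raise CompositionError(
            f"expected {len(catalog)} weights, got shape {w.shape}"
        )
    if not np.all(np.isfinite(w)):
        raise CompositionError("weights must be finite")
    if np.any(w < 0):
        bad = [catalog.names[i] for i in np.flatnonzero(w < 0)]
        raise CompositionError(f"negative weight for {bad}")
    s = float(w.sum())
    if abs(s - 1.0) > tol:
        raise CompositionError(
            f"weights sum to {s!r}, outside 1 +/- {tol}"
        )
    return CompositionVector(catalog, w / s)


def renormalize_known(comp: CompositionVector) -> CompositionVector:
    """Drop the residual "other" mass and rescale over the known varieties.

    Needed wherever a per-variety table covers only the 11 named varieties
    (e.g. nutritional values): each known weight is divided by
    ``1 - other_weight``.  A composition that is entirely residual has no
    defined renormalization and raises.
    """
    if not comp.catalog.includes_other:
        return comp
    other = comp.other_weight
    known = comp.weights[:-1]
    total = float(known.sum())
    if total <= 0.0:
        raise CompositionError("composition is entirely residual ('other')")
    # divide by the known-mass total rather than 1 - other so the result is
    # exactly on the simplex even after float rounding
    del other
    return CompositionVector(comp.catalog.without_other(), known / total)
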