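"""Stimulus sets for the ensemble-orientation experiments.

Each set holds six component orientations.  The four primary sets pair an
average tilt of +45° or -45° with ("w") or without ("w/o") an element at
the average itself; four dummy sets are shown only in the behavioral
adjustment experiment to keep observers from noticing the small number of
distinct displays, and are excluded from analysis.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .orientation import wrap_orientation

__all__ = [
    "StimulusSet",
    "set_average",
    "builtin_stimulus_sets",
    "stimulus_sets_by_name",
    "stimulus_sets_to_json",
    "stimulus_sets_from_json",
]


@dataclass(frozen=True)
class StimulusSet:
    """A named set of six component orientations (degrees)."""

    name: str
    components: tuple[float, ...]
    is_dummy: bool = False

    def __post_init__(self):
        if len(self.components) != 6:
            raise ValueError(
                f"a stimulus set has exactly six components, got {len(self.components)}"
            )
        object.__setattr__(self, "components", tuple(float(c) for c in self.components))

    @property
    def average(self) -> float:
        """Circular-mean average orientation of the components."""
        return set_average(self)

    @property
    def contains_average(self) -> bool:
        """True if an element equals the set average ("w" sets)."""
        avg = self.average
        return any(np.isclose(wrap_orientation(c), avg) for c in self.components)

    @property
    def set_type(self) -> str:
        """``"w"`` or ``"w/o"`` depending on the presence of the average."""
        return "w" if self.contains_average else "w/o"

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "components": list(self.components),
            "is_dummy": self.is_dummy,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StimulusSet":
        return cls(name=d["name"], components=tuple(d["components"]), is_dummy=bool(d["is_dummy"]))


def set_average(s) -> float:
    """Average orientation of a stimulus set, degrees in ``(-90, 90]``.

    Computed as the circular mean on doubled angles, the proper mean for
    axial (180°-periodic) data; for every built-in set this coincides with
    the arithmetic mean of the components.

    Parameters
    ----------
    s : StimulusSet or sequence of six orientations

    Raises
    ------
    ValueError
        If the doubled-angle resultant vanishes (e.g. balanced components
        at 0° and 90°), in which case the mean orientation is undefined.
    """
    comps = np.asarray(s.components if isinstance(s, StimulusSet) else s, dtype=float)
    doubled = np.deg2rad(2.0 * comps)
    z = np.mean(np.exp(1j * doubled))
    if np.abs(z) < 1e-9:
        raise ValueError("mean orientation is undefined: doubled-angle resultant is zero")
    return wrap_orientation(np.rad2deg(np.angle(z)) / 2.0)


_PRIMARY = [
    ("Average 45° w", (15, 15, 45, 45, 75, 75)),
    ("Average 45° w/o", (15, 15, 15, 75, 75, 75)),
    ("Average -45° w", (-15, -15, -45, -45, -75, -75)),
    ("Average -45° w/o", (-15, -15, -15, -75, -75, -75)),
]

_DUMMY = [
    ("Dummy -35°", (-5, -5, -35, -35, -65, -65)),
    ("Dummy 35°", (5, 5, 35, 35, 65, 65)),
    ("Dummy 45° narrow", (30, 30, 45, 45, 60, 60)),
    ("Dummy -45° narrow", (-30, -30, -45, -45, -60, -60)),
]


def builtin_stimulus_sets() -> list[StimulusSet]:
    """The eight built-in stimulus sets: four primary, four dummy."""
    sets = [StimulusSet(n, c, is_dummy=False) for n, c in _PRIMARY]
    sets += [StimulusSet(n, c, is_dummy=True) for n, c in _DUMMY]
    return sets


def stimulus_sets_by_name(include_dummies: bool = True) -> dict[str, StimulusSet]:
    """Mapping from set name to built-in :class:`StimulusSet`."""
    return {
        s.name: s for s in builtin_stimulus_sets() if include_dummies or not s.is_dummy
    }


def stimulus_sets_to_json(sets, path=None) -> str:
    """Serialize stimulus sets to a JSON text block (optionally to a file)."""
    text = json.dumps([s.to_dict() for s in sets], indent=2, ensure_ascii=False)
    if path is not None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(text + "\n")
    return text


def stimulus_sets_from_json(text_or_path) -> list[StimulusSet]:
    """Load stimulus sets from a JSON string or file path."""
    text = str(text_or_path)
    if not text.lstrip().startswith("["):
        with open(text_or_path, "r", encoding="utf-8") as fh:
            text = fh.read()
    return [StimulusSet.from_dict(d) for d in json.loads(text)]
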