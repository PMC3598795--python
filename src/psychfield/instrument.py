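"""Instrument schema: subscale structure, response scale, and file I/O.

An instrument is an ordered collection of subscales, each an ordered list of
items answered on a common ordinal response scale (default 0-4, "never a
problem" .. "almost always a problem").  The built-in default is the 16
subscale / 70 item adult neurofibromatosis type 1 HRQOL module; its Sexual
Functioning subscale is excluded from the Total Score and from the
reliability / multitrait analyses by default, leaving 15 analyzed subscales
and 67 analyzed items.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import yaml

__all__ = [
    "SubscaleSpec",
    "InstrumentSpec",
    "InstrumentError",
    "load_instrument",
    "save_instrument",
    "pedsql_nf1_adult",
    "BUILTIN_INSTRUMENTS",
]


class InstrumentError(ValueError):
    """Raised when an instrument definition violates the schema."""


@dataclass(frozen=True)
class SubscaleSpec:
    """One named subscale: an ordered list of (item_id, wording) pairs.

    ``sensitive`` marks subscales prone to block "not applicable" skips
    (whole-subscale missingness), e.g. Sexual Functioning.
    """

    name: str
    items: tuple[tuple[str, str], ...]
    sensitive: bool = False

    def __post_init__(self) -> None:
        if len(self.items) < 2:
            raise InstrumentError(
                f"subscale {self.name!r} has {len(self.items)} item(s); need >= 2"
            )

    @property
    def item_ids(self) -> tuple[str, ...]:
        return tuple(i for i, _ in self.items)

    @property
    def n_items(self) -> int:
        return len(self.items)


# respondent-metadata column names reserved in response CSVs
RESERVED_COLUMNS = ("id", "age", "health_status")


@dataclass(frozen=True)
class InstrumentSpec:
    name: str
    subscales: tuple[SubscaleSpec, ...]
    scale_points: tuple[int, ...] = (0, 1, 2, 3, 4)
    scale_labels: Mapping[int, str] = field(default_factory=dict)
    total_score_exclusions: frozenset[str] = frozenset({"Sexual Functioning"})

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for sub in self.subscales:
            for iid in sub.item_ids:
                if iid in seen:
                    raise InstrumentError(f"duplicate item id {iid!r}")
                if iid in RESERVED_COLUMNS:
                    raise InstrumentError(
                        f"item id {iid!r} collides with a reserved metadata column"
                    )
                seen.add(iid)
        names = [s.name for s in self.subscales]
        if len(set(names)) != len(names):
            raise InstrumentError("duplicate subscale names")
        unknown = set(self.total_score_exclusions) - set(names)
        if unknown:
            raise InstrumentError(
                f"total_score_exclusions name unknown subscales: {sorted(unknown)}"
            )
        if len(self.scale_points) < 2:
            raise InstrumentError("scale_points needs >= 2 admissible values")
        if list(self.scale_points) != sorted(set(self.scale_points)):
            raise InstrumentError("scale_points must be strictly increasing")

    # -- structure accessors -------------------------------------------------

    @property
    def item_ids(self) -> tuple[str, ...]:
        """All item ids, instrument order."""
        return tuple(i for s in self.subscales for i in s.item_ids)

    @property
    def n_items(self) -> int:
        return len(self.item_ids)

    def subscale(self, name: str) -> SubscaleSpec:
        for s in self.subscales:
            if s.name == name:
                return s
        raise KeyError(name)

    @property
    def analyzed_subscales(self) -> tuple[SubscaleSpec, ...]:
        """Subscales entering the Total Score and psychometric analyses."""
        return tuple(
            s for s in self.subscales if s.name not in self.total_score_exclusions
        )

    @property
    def analyzed_item_ids(self) -> tuple[str, ...]:
        return tuple(i for s in self.analyzed_subscales for i in s.item_ids)

    def owner_of(self, item_id: str) -> SubscaleSpec:
        """The subscale an item belongs to."""
        for s in self.subscales:
            if item_id in s.item_ids:
                return s
        raise KeyError(item_id)

    # -- serialisation -------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "scale_points": list(self.scale_points),
            "scale_labels": {int(k): v for k, v in self.scale_labels.items()},
            "total_score_exclusions": sorted(self.total_score_exclusions),
            "subscales": [
                {
                    "name": s.name,
                    "sensitive": s.sensitive,
                    "items": [{"id": i, "text": t} for i, t in s.items],
                }
                for s in self.subscales
            ],
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "InstrumentSpec":
        try:
            subscales = tuple(
                SubscaleSpec(
                    name=s["name"],
                    items=tuple((it["id"], it.get("text", "")) for it in s["items"]),
                    sensitive=bool(s.get("sensitive", False)),
                )
                for s in d["subscales"]
            )
            return cls(
                name=d["name"],
                subscales=subscales,
                scale_points=tuple(int(p) for p in d.get("scale_points", (0, 1, 2, 3, 4))),
                scale_labels={int(k): v for k, v in d.get("scale_labels", {}).items()},
                total_score_exclusions=frozenset(d.get("total_score_exclusions", ())),
            )
        except KeyError as e:  # missing required field
            raise InstrumentError(f"instrument definition missing field {e}") from e


def save_instrument(spec: InstrumentSpec, path: str | Path) -> None:
    """Write an instrument definition to YAML (.yaml/.yml) or JSON (.json)."""
    path = Path(path)
    d = spec.to_dict()
    if path.suffix == ".json":
        path.write_text(json.dumps(d, indent=2))
    else:
        path.write_text(yaml.safe_dump(d, sort_keys=False))


def load_instrument(source: str | Path) -> InstrumentSpec:
    """Load an instrument from a YAML/JSON file or by built-in name.

    ``load_instrument("pedsql_nf1_adult")`` returns the default 16-subscale,
    70-item adult NF1 module.
    """
    if isinstance(source, str) and source in BUILTIN_INSTRUMENTS:
        return BUILTIN_INSTRUMENTS[source]()
    path = Path(source)
    if not path.exists():
        raise InstrumentError(
            f"{source!r} is neither a built-in instrument name "
            f"({sorted(BUILTIN_INSTRUMENTS)}) nor an existing file"
        )
    text = path.read_text()
    d = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(d, Mapping):
        raise InstrumentError(f"{path}: top level must be a mapping")
    return InstrumentSpec.from_dict(d)


# ---------------------------------------------------------------------------
# Built-in default: adult NF1 HRQOL module, final 16-subscale / 70-item form
# ---------------------------------------------------------------------------

_SCALE_LABELS = {
    0: "never a problem",
    1: "almost never a problem",
    2: "sometimes a problem",
    3: "often a problem",
    4: "almost always a problem",
}


def _sub(name: str, prefix: str, wordings: Sequence[str], sensitive: bool = False) -> SubscaleSpec:
    return SubscaleSpec(
        name=name,
        items=tuple((f"{prefix}{i + 1}", w) for i, w in enumerate(wordings)),
        sensitive=sensitive,
    )


def pedsql_nf1_adult() -> InstrumentSpec:
    """The built-in adult NF1 module: 16 subscales, 70 items.

    Sexual Functioning is flagged sensitive (respondents may skip the whole
    block) and excluded from the Total Score and analyses by default.
    """
    return InstrumentSpec(
        name="pedsql_nf1_adult",
        scale_labels=_SCALE_LABELS,
        subscales=(
            _sub("Physical Functioning", "phys", [
                "Feeling physically weak",
                "Walking more than one block",
                "Climbing stairs",
                "Running",
                "Doing a sports activity or exercise",
                "Lifting something heavy",
                "Doing chores around the house",
            ]),
            _sub("Emotional Functioning", "emot", [
                "Feeling anxious",
                "Feeling sad",
                "Feeling angry",
                "Feeling frustrated",
                "Feeling helpless or hopeless",
            ]),
            _sub("Social Functioning", "soc", [
                "Getting support from others",
                "Having enough energy for social activities",
            ]),
            _sub("Cognitive Functioning", "cog", [
                "Keeping attention on things",
                "Remembering what people tell you",
                "Remembering what you just heard/read",
                "Thinking quickly",
                "Remembering what you were just thinking",
            ]),
            _sub("Communication", "comm", [
                "Telling the doctors and nurses how you feel",
                "Asking the doctors and nurses questions",
                "Talking with others about your disorder",
            ]),
            _sub("Worry", "worry", [
                "Worrying about my neurofibromas",
                "Worrying about side effects from medical treatments",
                "Worrying about whether or not medical treatments are working",
                "Worrying that neurofibromas will grow bigger or reoccur",
                "Worrying about my future or the risk of having children with "
                "Neurofibromatosis type 1",
                "Worrying about the risk of other health related issues associated "
                "with Neurofibromatosis type 1",
            ]),
            _sub("Perceived Physical Appearance", "appear", [
                "Feeling that I am not good looking",
                "Not wanting other people to see my neurofibromas",
                "Being embarrassed about others seeing my body",
            ]),
            _sub("Pain and Hurt", "pain", [
                "Aching or hurting",
                "Aching or hurting a lot",
                "Not sleeping because of pain",
            ]),
            _sub("Paresthesias", "pares", [
                "A burning sensation in some part of my body",
                "A tingling sensation in some part of my body",
            ]),
            _sub("Skin Irritation", "skin", [
                "Itching",
                "Itching a lot",
                "Getting a skin rash when exposed to sun",
                "Tolerating temperature changes",
                "Rough skin",
            ]),
            _sub("Sensation", "sens", [
                "Vision in one or both eyes",
                "Seeing well enough with glasses or contact lenses",
                "Hearing in one or both ears",
                "Speech",
            ]),
            _sub("Movement and Balance", "move", [
                "Bending my body",
                "Moving one or both legs",
                "Using or moving one or both arms",
                "Keeping balance when sitting or standing",
            ]),
            _sub("Daily Activities", "daily", [
                "Putting on shoes",
                "Buttoning my shirt",
                "Combing my hair",
                "Getting into the bathroom to use the toilet",
                "Undressing to use the toilet",
                "Getting in and out of bathtub or shower",
                "Brushing my teeth",
                "Eating with a fork and knife",
                "Using a phone",
                "Shopping",
                "Managing money",
                "Driving",
            ]),
            _sub("Fatigue", "fatig", [
                "Feeling tired",
                "Resting a lot",
                "Having enough energy to do things that I like to do",
            ]),
            _sub("Treatment Anxiety", "tanx", [
                "Getting scared about going to the doctor",
                "Getting scared about going to the hospital",
                "Being responsible for my medicines or therapy",
            ]),
            _sub("Sexual Functioning", "sex", [
                "Fatigue or lack of energy affecting your satisfaction with your sex life",
                "Pain affecting your satisfaction with your sex life",
                "Ability to have children with a fertile partner",
            ], sensitive=True),
        ),
    )


BUILTIN_INSTRUMENTS = {"pedsql_nf1_adult": pedsql_nf1_adult}
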