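"""Label constellations for intracranial-artery anatomical labeling.

Two class catalogs are used throughout the pipeline:

* the *detailed* constellation — 24 named arterial segments (13 base names,
  paired left/right except the midline AcomA and BA) plus background and
  non-annotated vessels, 26 classes in total;
* the *aggregated* constellation — the same segments grouped into 11
  clinically relevant territories plus the two auxiliary classes, 13 total.

Laterality follows the anatomical convention D- (dexter, right) / S-
(sinister, left).  Index order is a package convention: background 0,
non-annotated 1, then artery classes in catalog order, dexter before
sinister.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .grid import VolumeGrid

__all__ = [
    "LabelClass",
    "LabelTaxonomy",
    "build_detailed_taxonomy",
    "build_aggregated_taxonomy",
    "aggregate_labels",
    "BACKGROUND",
    "NON_ANNOTATED",
]

BACKGROUND = 0
NON_ANNOTATED = 1

# Base artery names in catalog order, with pairing flag.
_BASE_ARTERIES: list[tuple[str, str, bool]] = [
    # (code, description, paired)
    ("ICA", "internal carotid artery", True),
    ("ICA-CoW", "internal carotid artery, Circle of Willis segment", True),
    ("M1", "middle cerebral artery, first segment", True),
    ("M2-sup", "middle cerebral artery, second segment superior", True),
    ("M2-inf", "middle cerebral artery, second segment inferior", True),
    ("A1", "anterior cerebral artery, first segment", True),
    ("ACOM", "anterior communicating artery", False),
    ("A2", "anterior cerebral artery, second segment", True),
    ("VA", "vertebral artery", True),
    ("BA", "basilar artery", False),
    ("PCOM", "posterior communicating artery", True),
    ("P1", "posterior cerebral artery, first segment", True),
    ("P2", "posterior cerebral artery, second segment", True),
]

# Aggregated groups: (code, description, detailed member codes).
_AGG_GROUPS: list[tuple[str, str, list[str]]] = [
    ("D-ICA-grp", "right ICA territory (ICA, ICA CoW)", ["D-ICA", "D-ICA-CoW"]),
    ("S-ICA-grp", "left ICA territory (ICA, ICA CoW)", ["S-ICA", "S-ICA-CoW"]),
    ("D-MCA", "right MCA territory (M1, M2 sup, M2 inf)", ["D-M1", "D-M2-sup", "D-M2-inf"]),
    ("S-MCA", "left MCA territory (M1, M2 sup, M2 inf)", ["S-M1", "S-M2-sup", "S-M2-inf"]),
    ("D-ACA", "right ACA territory (A1, A2)", ["D-A1", "D-A2"]),
    ("S-ACA", "left ACA territory (A1, A2, AcomA)", ["S-A1", "S-A2", "ACOM"]),
    ("BA", "basilar artery", ["BA"]),
    ("D-VA", "right vertebral artery", ["D-VA"]),
    ("S-VA", "left vertebral artery", ["S-VA"]),
    ("D-PCA", "right PCA territory (PcomA, P1, P2)", ["D-PCOM", "D-P1", "D-P2"]),
    ("S-PCA", "left PCA territory (PcomA, P1, P2)", ["S-PCOM", "S-P1", "S-P2"]),
]


@dataclass(frozen=True)
class LabelClass:
    index: int
    code: str
    description: str


@dataclass
class LabelTaxonomy:
    """An ordered class catalog with optional detailed→aggregated mapping."""

    name: str
    classes: list[LabelClass]
    background_index: int = BACKGROUND
    nonannotated_index: int = NON_ANNOTATED
    aggregation_map: dict[int, int] | None = None

    def __post_init__(self) -> None:
        idx = [c.index for c in self.classes]
        if idx != list(range(len(idx))):
            raise ValueError("class indices must be consecutive from 0")
        codes = [c.code for c in self.classes]
        if len(set(codes)) != len(codes):
            raise ValueError("class codes must be unique")

    def __len__(self) -> int:
        return len(self.classes)

    @property
    def n_classes(self) -> int:
        return len(self.classes)

    @property
    def artery_indices(self) -> list[int]:
        aux = {self.background_index, self.nonannotated_index}
        return [c.index for c in self.classes if c.index not in aux]

    @property
    def auxiliary_indices(self) -> set[int]:
        return {self.background_index, self.nonannotated_index}

    def code(self, index: int) -> str:
        return self.classes[index].code

    def index_of(self, code: str) -> int:
        for c in self.classes:
            if c.code == code:
                return c.index
        raise KeyError(code)

    # -- serialization ------------------------------------------------------
    def to_dict(self) -> dict:
        d = {
            "name": self.name,
            "classes": [
                {"index": c.index, "code": c.code, "description": c.description}
                for c in self.classes
            ],
            "background_index": self.background_index,
            "nonannotated_index": self.nonannotated_index,
        }
        if self.aggregation_map is not None:
            d["aggregation_map"] = {str(k): v for k, v in self.aggregation_map.items()}
        return d

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_dict(cls, d: dict) -> "LabelTaxonomy":
        agg = d.get("aggregation_map")
        return cls(
            name=d["name"],
            classes=[LabelClass(c["index"], c["code"], c["description"]) for c in d["classes"]],
            background_index=d["background_index"],
            nonannotated_index=d["nonannotated_index"],
            aggregation_map={int(k): v for k, v in agg.items()} if agg else None,
        )

    @classmethod
    def from_json(cls, path) -> "LabelTaxonomy":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def _detailed_codes() -> list[tuple[str, str]]:
    out: list[tuple[str, str]] = []
    for code, desc, paired in _BASE_ARTERIES:
        if paired:
            out.append((f"D-{code}", f"right {desc}"))
            out.append((f"S-{code}", f"left {desc}"))
        else:
            out.append((code, desc))
    return out


def build_detailed_taxonomy() -> LabelTaxonomy:
    """The 26-class detailed constellation.

    24 arterial segment classes (13 base names, all paired into D-/S-
    variants except the unpaired AcomA and BA) plus background and
    non-annotated vessels.  The aggregation map onto the aggregated
    constellation is attached.
    """
    classes = [
        LabelClass(BACKGROUND, "BG", "background"),
        LabelClass(NON_ANNOTATED, "NA", "non-annotated vessel"),
    ]
    for code, desc in _detailed_codes():
        classes.append(LabelClass(len(classes), code, desc))

    tax = LabelTaxonomy("detailed", classes)
    agg = build_aggregated_taxonomy()
    amap = {BACKGROUND: BACKGROUND, NON_ANNOTATED: NON_ANNOTATED}
    for gcode, _desc, members in _AGG_GROUPS:
        for m in members:
            amap[tax.index_of(m)] = agg.index_of(gcode)
    tax.aggregation_map = amap
    return tax


def build_aggregated_taxonomy() -> LabelTaxonomy:
    """The 13-class aggregated constellation (11 territories + auxiliaries)."""
    classes = [
        LabelClass(BACKGROUND, "BG", "background"),
        LabelClass(NON_ANNOTATED, "NA", "non-annotated vessel"),
    ]
    for code, desc, _members in _AGG_GROUPS:
        classes.append(LabelClass(len(classes), code, desc))
    return LabelTaxonomy("aggregated", classes)


def aggregate_labels(labels: VolumeGrid, taxonomy: LabelTaxonomy) -> VolumeGrid:
    """Map a detailed label volume voxel-wise onto the aggregated classes.

    ``taxonomy`` must be the detailed taxonomy (it carries the aggregation
    map).  Shape and spacing are preserved; an index outside the detailed
    catalog is rejected.
    """
    if taxonomy.aggregation_map is None:
        raise ValueError(f"taxonomy '{taxonomy.name}' carries no aggregation map")
    data = np.asarray(labels.data)
    if not np.issubdtype(data.dtype, np.integer):
        raise ValueError("label volume must have an integer dtype")
    lo, hi = int(data.min(initial=0)), int(data.max(initial=0))
    if lo < 0 or hi >= taxonomy.n_classes:
        bad = lo if lo < 0 else hi
        raise ValueError(f"label volume contains unknown detailed index {bad}")
    lut = np.empty(taxonomy.n_classes, dtype=data.dtype)
    for k, v in taxonomy.aggregation_map.items():
        lut[k] = v
    return labels.with_data(lut[data])
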