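"""The ordered, named feature scheme.

The full vector is the concatenation of three blocks:

* 122 base features — length, the 20 residue frequencies, the 20
  per-residue maximum consecutive runs, frequency and maximum run for each
  of the 34 documented residue groups, absolute charge per residue,
  isoelectric point, and the 11 predicted/derived properties;
* 7,381 interactive features — one per unordered pair of base features,
  defined as the product of the two raw base values;
* 400 dipeptide occurrence features — overlapping counts of every ordered
  residue pair.

The base list is configurable (groups can be swapped via config), but any
edit that changes its cardinality away from 122 fails validation, which
keeps the full-vector arithmetic (122 + 7,381 + 400 = 7,903) intact.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import yaml

from ..errors import InvalidArgumentError
from .properties import PROPERTY_NAMES
from .records import ResidueGroup
from .scales import ALPHABET, GROUP_DEFINITIONS

EXPECTED_BASE = 122
EXPECTED_INTERACTIVE = EXPECTED_BASE * (EXPECTED_BASE - 1) // 2  # 7,381
EXPECTED_DIPEPTIDE = 400
EXPECTED_TOTAL = EXPECTED_BASE + EXPECTED_INTERACTIVE + EXPECTED_DIPEPTIDE  # 7,903


@dataclass(frozen=True)
class FeatureDef:
    """One base feature: a display name plus a computation kind and key."""

    name: str
    kind: str  # length | aa_freq | aa_run | group_freq | group_run | abs_charge | pi | property
    key: str = ""


def default_groups() -> tuple[ResidueGroup, ...]:
    return tuple(
        ResidueGroup(name, frozenset(members)) for name, members in GROUP_DEFINITIONS
    )


def _build_base_defs(groups: Sequence[ResidueGroup]) -> tuple[FeatureDef, ...]:
    defs: list[FeatureDef] = [FeatureDef("length", "length")]
    defs.extend(FeatureDef(f"freq_{aa}", "aa_freq", aa) for aa in ALPHABET)
    defs.extend(FeatureDef(f"run_{aa}", "aa_run", aa) for aa in ALPHABET)
    for group in groups:
        defs.append(FeatureDef(f"gfreq_{group.name}", "group_freq", group.name))
        defs.append(FeatureDef(f"grun_{group.name}", "group_run", group.name))
    defs.append(FeatureDef("abs_charge_per_residue", "abs_charge"))
    defs.append(FeatureDef("isoelectric_point", "pi"))
    defs.extend(FeatureDef(prop, "property", prop) for prop in PROPERTY_NAMES)
    return tuple(defs)


class FeatureRegistry:
    """Ordered registry of base, interactive and dipeptide features."""

    def __init__(self, groups: Sequence[ResidueGroup] | None = None):
        self.groups: tuple[ResidueGroup, ...] = (
            tuple(groups) if groups is not None else default_groups()
        )
        self.base_defs = _build_base_defs(self.groups)
        self.base_names: tuple[str, ...] = tuple(d.name for d in self.base_defs)
        iu, ju = np.triu_indices(len(self.base_defs), k=1)
        self._pair_i = iu
        self._pair_j = ju
        self.dipeptide_names: tuple[str, ...] = tuple(
            f"dp_{a}{b}" for a in ALPHABET for b in ALPHABET
        )
        self._all_names: tuple[str, ...] | None = None
        self._index: dict[str, int] | None = None
        self.validate()

    # -- cardinalities -------------------------------------------------
    @property
    def n_base(self) -> int:
        return len(self.base_defs)

    @property
    def n_interactive(self) -> int:
        return len(self._pair_i)

    @property
    def n_dipeptide(self) -> int:
        return len(self.dipeptide_names)

    @property
    def n_total(self) -> int:
        return self.n_base + self.n_interactive + self.n_dipeptide

    @property
    def interactive_pairs(self) -> list[tuple[int, int]]:
        """Unordered base-feature index pairs (i < j), registry order."""
        return list(zip(self._pair_i.tolist(), self._pair_j.tolist()))

    @property
    def interactive_names(self) -> tuple[str, ...]:
        return tuple(
            f"{self.base_names[i]}*{self.base_names[j]}"
            for i, j in zip(self._pair_i, self._pair_j)
        )

    @property
    def all_names(self) -> tuple[str, ...]:
        if self._all_names is None:
            self._all_names = self.base_names + self.interactive_names + self.dipeptide_names
        return self._all_names

    def index_of(self, name: str) -> int:
        if self._index is None:
            self._index = {n: i for i, n in enumerate(self.all_names)}
        try:
            return self._index[name]
        except KeyError:
            raise InvalidArgumentError(f"unknown feature name: {name!r}") from None

    def interactive_name(self, base_a: str, base_b: str) -> str:
        """Canonical product-feature name for two base features."""
        ia = self.base_names.index(base_a)
        ib = self.base_names.index(base_b)
        if ia == ib:
            raise InvalidArgumentError(f"self-pair not allowed: {base_a!r}")
        if ia > ib:
            base_a, base_b = base_b, base_a
        return f"{base_a}*{base_b}"

    def group(self, name: str) -> ResidueGroup:
        for group in self.groups:
            if group.name == name:
                return group
        raise InvalidArgumentError(f"unknown residue group: {name!r}")

    # -- validation ----------------------------------------------------
    def validate(self) -> None:
        if self.n_base != EXPECTED_BASE:
            raise InvalidArgumentError(
                f"base feature count is {self.n_base}, expected {EXPECTED_BASE}; "
                "edit the group list so that 54 fixed features + 2 per group total 122"
            )
        if self.n_interactive != EXPECTED_INTERACTIVE:
            raise InvalidArgumentError(
                f"interactive count {self.n_interactive} != {EXPECTED_INTERACTIVE}"
            )
        if self.n_dipeptide != EXPECTED_DIPEPTIDE:
            raise InvalidArgumentError(
                f"dipeptide count {self.n_dipeptide} != {EXPECTED_DIPEPTIDE}"
            )
        names = self.base_names + self.dipeptide_names
        if len(set(names)) != len(names):
            raise InvalidArgumentError("duplicate feature names in registry")
        pairs = set(zip(self._pair_i.tolist(), self._pair_j.tolist()))
        if len(pairs) != self.n_interactive or any(i >= j for i, j in pairs):
            raise InvalidArgumentError("interactive pair index audit failed")

    # -- serialization -------------------------------------------------
    def to_config(self) -> dict:
        return {
            "groups": {g.name: "".join(sorted(g.members)) for g in self.groups},
        }

    @classmethod
    def from_config(cls, config: dict) -> "FeatureRegistry":
        groups_cfg = config.get("groups")
        if groups_cfg is None:
            return cls()
        groups = tuple(
            ResidueGroup(name, frozenset(members)) for name, members in groups_cfg.items()
        )
        return cls(groups)

    def to_yaml(self, path) -> None:
        with open(path, "w") as handle:
            yaml.safe_dump(self.to_config(), handle, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "FeatureRegistry":
        with open(path) as handle:
            return cls.from_config(yaml.safe_load(handle) or {})
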