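"""Mass-action reaction network for iron-mediated dopamine oxidation.

The model couples three groups of elementary processes, each parameterized by
conditional rate constants at pH 6.5, 7.0 and 7.4:

* autoxidation of dopamine (DA) through the semiquinone radical (DA^.-),
  dopamine o-quinone (DAQ), leukoaminochrome (DAL) and aminochrome (DAC),
  reactions 1-9;
* Fe(III) chemistry: ferrihydrite-like precipitation (AFO), dopamine-induced
  dissolution, mono-/bis-catecholate complexation and ligand-to-metal charge
  transfer, reactions 10-20;
* Fe(II) chemistry: oxygenation, Fenton chemistry, complexation and oxidation
  of the Fe(II)-dopamine complex, reactions 21-29.

Protons are implicit: pH enters only through the conditional rate-constant
columns.  AFO (amorphous ferric oxyhydroxide) is tracked in Fe-monomer
equivalents, so the Fe(III) dimerization (reaction 10) produces two monomer
equivalents and the surface reactions (11, 12, 19) consume one per event;
this keeps the iron budget exactly conserved.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

__all__ = [
    "PH_LABELS",
    "SPECIES",
    "FE_BUDGET",
    "SKELETON_BUDGET",
    "Reaction",
    "ReactionNetwork",
    "SpeciationWeights",
    "ValidationReport",
    "ConfigurationError",
    "build_network",
    "validate_network",
    "apparent_rate_constant",
    "network_to_json",
    "network_from_json",
    "default_table_document",
]

PH_LABELS: tuple[float, ...] = (6.5, 7.0, 7.4)

#: The 16 chemical species tracked by the model (concentrations in molar).
SPECIES: tuple[str, ...] = (
    "DA", "DA_rad", "DAQ", "DAL", "DAC", "DecayProducts",
    "O2", "O2_rad", "H2O2", "OH_rad",
    "FeII", "FeIII", "AFO", "FeIIDA", "FeIIIDA", "FeIIIDA2",
)

#: Iron atoms carried by each species.
FE_BUDGET: dict[str, int] = {
    "FeII": 1, "FeIII": 1, "AFO": 1, "FeIIDA": 1, "FeIIIDA": 1, "FeIIIDA2": 1,
}

#: Catechol skeletons carried by each species (the bis complex carries two;
#: the aminochrome decay sink counts as one so the budget closes).
SKELETON_BUDGET: dict[str, int] = {
    "DA": 1, "DA_rad": 1, "DAQ": 1, "DAL": 1, "DAC": 1, "DecayProducts": 1,
    "FeIIDA": 1, "FeIIIDA": 1, "FeIIIDA2": 2,
}


class ConfigurationError(ValueError):
    """Raised for invalid pH labels, unknown reactions or bad overrides."""


# Raw table: (id, reactants, products, forward constants, reverse constants).
# A scalar spans all three pH columns; a dict gives per-pH conditional values.
# Units: per M s for bimolecular steps, per s for unimolecular steps.
_RAW_TABLE: list[tuple] = [
    (1, ("DA", "O2"), ("O2_rad", "DA_rad"),
     {6.5: 3.94e-3, 7.0: 4.22e-3, 7.4: 8.24e-3}, None),
    (2, ("DA_rad", "O2"), ("O2_rad", "DAQ"), 2.95e3, 1.0e9),
    (3, ("DA_rad", "DA_rad"), ("DA", "DAQ"), 2.35e8, None),
    (4, ("DAQ",), ("DAL",), {6.5: 1.23e-2, 7.0: 1.0, 7.4: 4.45}, None),
    (5, ("DAL", "DAQ"), ("DA", "DAC"), 5.30e6, None),
    (6, ("DAL", "O2"), ("DAC", "H2O2"), {6.5: 1.17, 7.0: 1.31, 7.4: 5.12}, None),
    (7, ("O2_rad", "O2_rad"), ("H2O2", "O2"),
     {6.5: 1.90e6, 7.0: 6.0e5, 7.4: 1.90e5}, None),
    (8, ("DA_rad", "O2_rad"), ("DAQ", "H2O2"), 8.27e9, None),
    (9, ("DAC",), ("DecayProducts",),
     {6.5: 1.2e-6, 7.0: 8e-5, 7.4: 4e-4}, None),
    # AFO is in Fe-monomer equivalents: 2 Fe(III) -> 2 AFO.
    (10, ("FeIII", "FeIII"), ("AFO", "AFO"),
     {6.5: 1.0e6, 7.0: 3.4e6, 7.4: 5.0e6}, None),
    (11, ("AFO", "DA"), ("FeIIIDA",), {6.5: 0.599, 7.0: 2.3, 7.4: 2.34}, None),
    (12, ("AFO", "DA"), ("FeII", "DA_rad"),
     {6.5: 0.008, 7.0: 0.3, 7.4: 0.6}, None),
    (13, ("FeIII", "DA"), ("FeIIIDA",),
     {6.5: 8.7e4, 7.0: 2.09e5, 7.4: 4.15e5},
     {6.5: 1.45, 7.0: 0.969, 7.4: 0.463}),
    (14, ("FeIIIDA", "DA"), ("FeIIIDA2",),
     4.50e5, {6.5: 3.37e-4, 7.0: 2.86e-4, 7.4: 2.59e-4}),
    (15, ("FeIIIDA", "O2_rad"), ("FeIIDA", "O2"), 1.50e8, None),
    (16, ("FeIIIDA",), ("FeII", "DA_rad"), 0.23, None),
    (17, ("FeIIIDA2",), ("FeII", "DA", "DA_rad"), 7.26e-5, None),
    (18, ("FeIII", "O2_rad"), ("FeII", "O2"), 1.50e8, None),
    (19, ("AFO", "O2_rad"), ("FeII", "O2"),
     {6.5: 4.84e4, 7.0: 3.70e5, 7.4: 3.70e5}, None),
    (20, ("FeIII", "DA_rad"), ("FeII", "DAQ"), 9.12e9, None),
    (21, ("FeII", "O2"), ("FeIII", "O2_rad"),
     {6.5: 0.0209, 7.0: 0.0959, 7.4: 0.77}, None),
    (22, ("FeII", "O2_rad"), ("FeIII", "H2O2"), 1.0e7, None),
    (23, ("FeII", "H2O2"), ("FeIII", "OH_rad"),
     {6.5: 1.72e3, 7.0: 4.79e3, 7.4: 1.33e4}, None),
    (24, ("FeII", "DA"), ("FeIIDA",),
     {6.5: 7.0e2, 7.0: 7.2e2, 7.4: 7.5e2},
     {6.5: 1.02e-2, 7.0: 9.2e-3, 7.4: 1.6e-3}),
    (25, ("FeIIDA", "O2"), ("FeIIIDA", "O2_rad"),
     {6.5: 3.32, 7.0: 19.0, 7.4: 145.0}, None),
    (26, ("FeIIDA", "H2O2"), ("FeIIIDA", "OH_rad"),
     {6.5: 1.72e3, 7.0: 4.79e3, 7.4: 1.33e4}, None),
    (27, ("FeIIDA", "O2_rad"), ("FeIIIDA", "H2O2"), 1.0e7, None),
    (28, ("FeIIDA", "DA_rad"), ("FeIIIDA", "DA"), 1.92e5, None),
    # One-electron reduction of the semiquinone by free Fe(II); same rate
    # constant as the complexed analogue (reaction 28).
    (29, ("FeII", "DA_rad"), ("FeIII", "DA"), 1.92e5, None),
]

N_REACTIONS = 29


def _as_ph_map(value) -> dict[float, float]:
    if isinstance(value, Mapping):
        return {float(k): float(v) for k, v in value.items()}
    return {ph: float(value) for ph in PH_LABELS}


@dataclass(frozen=True)
class Reaction:
    """One mass-action reaction with pH-conditional rate constants.

    ``rate_constants`` maps each pH label to the forward constant; for the
    four reversible steps ``reverse_rate_constants`` carries the backward
    constant the same way.
    """

    id: int
    reactants: tuple[str, ...]
    products: tuple[str, ...]
    rate_constants: dict[float, float]
    reverse_rate_constants: dict[float, float] | None = None

    @property
    def reversible(self) -> bool:
        return self.reverse_rate_constants is not None

    def budget_delta(self, budget: Mapping[str, int]) -> int:
        before = sum(budget.get(s, 0) for s in self.reactants)
        after = sum(budget.get(s, 0) for s in self.products)
        return after - before


def _build_reactions() -> tuple[Reaction, ...]:
    out = []
    for rid, reac, prod, kf, kr in _RAW_TABLE:
        out.append(Reaction(
            id=rid, reactants=tuple(reac), products=tuple(prod),
            rate_constants=_as_ph_map(kf),
            reverse_rate_constants=_as_ph_map(kr) if kr is not None else None,
        ))
    return tuple(out)


REACTIONS: tuple[Reaction, ...] = _build_reactions()


def _parse_param_key(key) -> tuple[int, str]:
    """Normalize an override/parameter key to ``(reaction_id, direction)``.

    Accepts an integer id (forward), or strings like ``"13"``, ``"13f"``,
    ``"13r"``.
    """
    if isinstance(key, int):
        return key, "f"
    s = str(key).strip().lower()
    direction = "f"
    if s and s[-1] in ("f", "r"):
        direction, s = s[-1], s[:-1]
    try:
        rid = int(s)
    except ValueError:
        raise ConfigurationError(f"unparseable reaction key: {key!r}") from None
    return rid, direction


@dataclass(frozen=True)
class ReactionNetwork:
    """The 29-reaction network resolved at one pH label.

    ``k_forward``/``k_reverse`` are indexed by reaction id; irreversible
    reactions have no entry in ``k_reverse``.
    """

    ph_label: float
    reactions: tuple[Reaction, ...]
    k_forward: dict[int, float]
    k_reverse: dict[int, float]
    species: tuple[str, ...] = SPECIES

    def k(self, reaction_id: int) -> float:
        if reaction_id not in self.k_forward:
            raise ConfigurationError(f"no reaction {reaction_id}")
        return self.k_forward[reaction_id]

    def k_rev(self, reaction_id: int) -> float:
        if reaction_id not in self.k_reverse:
            raise ConfigurationError(f"reaction {reaction_id} is irreversible")
        return self.k_reverse[reaction_id]

    def reaction(self, reaction_id: int) -> Reaction:
        for r in self.reactions:
            if r.id == reaction_id:
                return r
        raise ConfigurationError(f"no reaction {reaction_id}")

    def content_hash(self) -> str:
        """Stable hash of the resolved constants, for provenance blocks."""
        import hashlib
        doc = json.dumps(
            {"ph": self.ph_label, "kf": self.k_forward, "kr": self.k_reverse},
            sort_keys=True,
        )
        return hashlib.sha256(doc.encode()).hexdigest()[:16]


def _resolve_ph(reaction: Reaction, ph_label: float, interpolate: bool,
                reverse: bool = False) -> float | None:
    table = reaction.reverse_rate_constants if reverse else reaction.rate_constants
    if table is None:
        return None
    if ph_label in table:
        return table[ph_label]
    if not interpolate:
        raise ConfigurationError(
            f"unknown pH label {ph_label!r}; valid labels are {PH_LABELS} "
            "(pass interpolate=True for experimental log-linear interpolation)"
        )
    if not (PH_LABELS[0] <= ph_label <= PH_LABELS[-1]):
        raise ConfigurationError(
            f"pH {ph_label} outside the tabulated range {PH_LABELS[0]}-{PH_LABELS[-1]}"
        )
    # log-linear over the bracketing tabulated columns
    phs = sorted(table)
    for lo, hi in zip(phs, phs[1:]):
        if lo <= ph_label <= hi:
            w = (ph_label - lo) / (hi - lo)
            return 10 ** ((1 - w) * math.log10(table[lo]) + w * math.log10(table[hi]))
    raise ConfigurationError(f"cannot interpolate pH {ph_label}")


def build_network(ph_label: float, overrides: Mapping | None = None,
                  interpolate: bool = False) -> ReactionNetwork:
    """Resolve the shipped rate-constant tables at one pH label.

    Parameters
    ----------
    ph_label
        One of 6.5, 7.0, 7.4.  Intermediate values are only accepted with
        ``interpolate=True`` (experimental log-linear interpolation between
        the tabulated columns).
    overrides
        Optional map from reaction key to a replacement rate constant.  Keys
        are reaction ids (forward) or strings such as ``"13r"`` for the
        reverse constant of a reversible reaction.
    """
    ph_label = float(ph_label)
    valid_ids = {r.id for r in REACTIONS}
    kf: dict[int, float] = {}
    kr: dict[int, float] = {}
    for r in REACTIONS:
        kf[r.id] = _resolve_ph(r, ph_label, interpolate)
        if r.reversible:
            kr[r.id] = _resolve_ph(r, ph_label, interpolate, reverse=True)
    if overrides:
        for key, value in overrides.items():
            rid, direction = _parse_param_key(key)
            if rid not in valid_ids:
                raise ConfigurationError(f"override on nonexistent reaction {rid}")
            value = float(value)
            if direction == "f":
                kf[rid] = value
            else:
                if rid not in kr:
                    raise ConfigurationError(
                        f"reverse override on irreversible reaction {rid}")
                kr[rid] = value
    return ReactionNetwork(ph_label=ph_label, reactions=REACTIONS,
                           k_forward=kf, k_reverse=kr)


@dataclass
class ValidationReport:
    """Collected invariant violations; empty means the network is valid."""

    problems: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.problems

    def __bool__(self) -> bool:  # truthy when valid, like a passing check
        return self.ok


def validate_network(net: ReactionNetwork) -> ValidationReport:
    """Check conservation budgets and rate-constant positivity."""
    report = ValidationReport()
    species = set(net.species)
    for r in net.reactions:
        for s in r.reactants + r.products:
            if s not in species:
                report.problems.append(f"reaction {r.id}: unknown species {s}")
        d_fe = r.budget_delta(FE_BUDGET)
        if d_fe != 0:
            report.problems.append(
                f"reaction {r.id}: Fe budget changes by {d_fe}")
        d_skel = r.budget_delta(SKELETON_BUDGET)
        if d_skel != 0:
            report.problems.append(
                f"reaction {r.id}: catechol-skeleton budget changes by {d_skel}")
    for rid, k in net.k_forward.items():
        if not k > 0:
            report.problems.append(f"reaction {rid}: nonpositive forward k={k}")
    for rid, k in net.k_reverse.items():
        if not k > 0:
            report.problems.append(f"reaction {rid}: nonpositive reverse k={k}")
    return report


@dataclass(frozen=True)
class SpeciationWeights:
    """Acid-base speciation of dopamine with intrinsic oxygenation constants.

    ``alpha`` holds the fractions of total dopamine present as H2DA, HDA- and
    DA2-; ``k_intrinsic`` the matching intrinsic rate constants for reaction
    with O2 (per M s).  The conditional (apparent) oxygenation constant is the
    speciation-weighted sum of the intrinsic ones.
    """

    alpha: tuple[float, float, float]
    k_intrinsic: tuple[float, float, float]

    def __post_init__(self):
        if len(self.alpha) != 3 or len(self.k_intrinsic) != 3:
            raise ValueError("alpha and k_intrinsic must have three entries")
        for a in self.alpha:
            if not (0.0 <= a <= 1.0):
                raise ValueError(f"fraction {a} outside [0, 1]")
        if abs(sum(self.alpha) - 1.0) > 1e-9:
            raise ValueError("speciation fractions must sum to 1")


def apparent_rate_constant(w: SpeciationWeights) -> float:
    """k_app = sum_i alpha_i * k_i over the three protonation states."""
    return float(sum(a * k for a, k in zip(w.alpha, w.k_intrinsic)))


# --------------------------------------------------------------------------
# JSON serialization

def default_table_document() -> dict:
    """The full rate-constant tables as a plain JSON-able document."""
    doc = {"species": list(SPECIES), "ph_labels": list(PH_LABELS), "reactions": []}
    for r in REACTIONS:
        entry = {
            "id": r.id,
            "reactants": list(r.reactants),
            "products": list(r.products),
            "rate_constants": {str(ph): r.rate_constants[ph] for ph in PH_LABELS},
        }
        if r.reversible:
            entry["reverse_rate_constants"] = {
                str(ph): r.reverse_rate_constants[ph] for ph in PH_LABELS}
        doc["reactions"].append(entry)
    return doc


def network_to_json(path: str | Path | None = None) -> str:
    """Serialize the shipped tables; optionally write to ``path``."""
    text = json.dumps(default_table_document(), indent=1)
    if path is not None:
        Path(path).write_text(text)
    return text


def network_from_json(source: str | Path) -> tuple[Reaction, ...]:
    """Load a reaction table document (as written by :func:`network_to_json`)."""
    if isinstance(source, Path):
        doc = json.loads(source.read_text())
    else:
        try:
            doc = json.loads(str(source))
        except json.JSONDecodeError:
            doc = json.loads(Path(source).read_text())
    reactions = []
    for entry in doc["reactions"]:
        reactions.append(Reaction(
            id=int(entry["id"]),
            reactants=tuple(entry["reactants"]),
            products=tuple(entry["products"]),
            rate_constants={float(k): float(v)
                            for k, v in entry["rate_constants"].items()},
            reverse_rate_constants=(
                {float(k): float(v)
                 for k, v in entry["reverse_rate_constants"].items()}
                if "reverse_rate_constants" in entry else None),
        ))
    return tuple(reactions)
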