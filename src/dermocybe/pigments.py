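"""Anthraquinone pigment reference library, species profiles and pigment groups.

Dermocyboid *Cortinarius* species owe their colours to a small set of
anthraquinone pigments.  Fifteen annotated compounds (emodin-1,6-di-glycoside
through 7,7'-biphyscion, numbered 1-15) are used here as semi-quantitative
taxonomic characters: each species profile records, per pigment, whether it is
absent, a trace pigment (relative peak height below 10% of the tallest
chromatogram peak) or a main pigment (at or above 10%).

The module ships the curated reference data (library, fifteen species
profiles and the four pigment groups Croceus / Malicorius / Ominosus /
Sanguineus) and implements profile dissimilarity (Bray-Curtis), rule-plus-
centroid group assignment, and ranked species matching for query profiles.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

PIGMENT_IDS = tuple(range(1, 16))

#: Numeric weights standing in for unpublished relative quantities: band
#: midpoints of the trace (<10%) and main (>=10%) relative-height classes.
LEVEL_WEIGHTS = {"absent": 0.0, "trace": 5.0, "main": 55.0}

LEVELS = ("absent", "trace", "main")


@dataclass(frozen=True)
class PigmentCompound:
    """One annotated anthraquinone.

    ``reference_rt`` is a fixed synthetic retention time (minutes) used by the
    chromatogram simulator and the peak annotator; ``channel_weights`` split
    the compound's absorbance across the 428/478/519 nm detector channels and
    sum to one.
    """

    id: int
    name: str
    reference_rt: float
    channel_weights: tuple[float, float, float]


class PigmentLibrary:
    """The 15-compound reference library, indexable by pigment id."""

    def __init__(self, compounds: list[PigmentCompound]):
        ids = [c.id for c in compounds]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate pigment ids in library")
        names = [c.name for c in compounds]
        if len(set(names)) != len(names):
            raise ValueError("duplicate pigment names in library")
        for c in compounds:
            w = np.asarray(c.channel_weights, dtype=float)
            if (w < 0).any() or abs(w.sum() - 1.0) > 1e-9:
                raise ValueError(
                    f"channel weights of pigment {c.id} must be non-negative "
                    "and sum to 1"
                )
        self._by_id = {c.id: c for c in sorted(compounds, key=lambda c: c.id)}

    def __len__(self) -> int:
        return len(self._by_id)

    def __contains__(self, pigment_id: int) -> bool:
        return pigment_id in self._by_id

    def __getitem__(self, pigment_id: int) -> PigmentCompound:
        return self._by_id[pigment_id]

    def __iter__(self):
        return iter(self._by_id.values())

    @property
    def ids(self) -> list[int]:
        return list(self._by_id)

    def retention_times(self) -> np.ndarray:
        return np.array([c.reference_rt for c in self])

    def min_rt_spacing(self) -> float:
        rts = np.sort(self.retention_times())
        return float(np.diff(rts).min()) if len(rts) > 1 else np.inf


@dataclass
class SpeciesPigmentProfile:
    """Semi-quantitative pigment profile of one species or one specimen.

    ``levels`` maps pigment id -> "trace" | "main" (absent pigments are
    simply missing).  ``quantities`` optionally carries measured relative
    heights in percent of the tallest peak; ``unknown_peaks`` lists retention
    times of called peaks that matched no library compound (e.g. the
    unidentified *C. ominosus* pigment near 5.5 min), which are reported but
    excluded from all distance computations.
    """

    species: str
    levels: dict[int, str] = field(default_factory=dict)
    quantities: dict[int, float] | None = None
    unknown_peaks: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        for pid, level in self.levels.items():
            if level not in ("trace", "main"):
                raise ValueError(f"invalid level {level!r} for pigment {pid}")
        if self.levels and "main" not in self.levels.values():
            raise ValueError(
                f"profile {self.species!r} has pigments but no main pigment"
            )
        if self.quantities is not None:
            for pid, q in self.quantities.items():
                if not 0 < q <= 100:
                    raise ValueError(f"relative quantity of pigment {pid} not in (0, 100]")
                level = self.levels.get(pid)
                if level == "trace" and q >= 10:
                    raise ValueError(f"trace pigment {pid} with quantity {q} >= 10%")
                if level == "main" and q < 10:
                    raise ValueError(f"main pigment {pid} with quantity {q} < 10%")

    @property
    def present(self) -> set[int]:
        return set(self.levels)

    def level(self, pigment_id: int) -> str:
        return self.levels.get(pigment_id, "absent")

    def to_dict(self) -> dict:
        return {
            "species": self.species,
            "levels": {str(pid): lvl for pid, lvl in sorted(self.levels.items())},
            "quantities": (
                {str(pid): q for pid, q in sorted(self.quantities.items())}
                if self.quantities
                else None
            ),
            "unknown_peaks": list(self.unknown_peaks),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SpeciesPigmentProfile":
        return cls(
            species=d.get("species", ""),
            levels={int(k): v for k, v in d.get("levels", {}).items()},
            quantities=(
                {int(k): float(v) for k, v in d["quantities"].items()}
                if d.get("quantities")
                else None
            ),
            unknown_peaks=[float(x) for x in d.get("unknown_peaks", [])],
        )

    def weight_vector(self, use_quantities: bool = True) -> np.ndarray:
        """Profile as a length-15 non-negative weight vector.

        Measured relative quantities are used when available, otherwise the
        level-band midpoints from :data:`LEVEL_WEIGHTS`.
        """
        w = np.zeros(len(PIGMENT_IDS))
        for i, pid in enumerate(PIGMENT_IDS):
            if use_quantities and self.quantities and pid in self.quantities:
                w[i] = self.quantities[pid]
            else:
                w[i] = LEVEL_WEIGHTS[self.level(pid)]
        return w


@dataclass(frozen=True)
class PigmentGroup:
    """One of the four pigment groups, as a constraint rule plus curated members."""

    name: str
    required: frozenset[int]
    forbidden: frozenset[int]
    any_of: tuple[frozenset[int], ...]
    members: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.required & self.forbidden:
            raise ValueError(f"group {self.name}: required and forbidden overlap")

    def admits(self, profile: SpeciesPigmentProfile) -> bool:
        """Stage-1 constraint filter: required present, forbidden absent."""
        present = profile.present
        if not self.required <= present:
            return False
        if self.forbidden & present:
            return False
        return all(alt & present for alt in self.any_of)


def _data_text(name: str) -> str:
    return resources.files("dermocybe.data").joinpath(name).read_text(encoding="utf-8")


def load_library() -> PigmentLibrary:
    """Load the packaged 15-compound pigment library."""
    compounds = []
    lines = _data_text("pigments.tsv").strip().splitlines()
    header = lines[0].split("\t")
    assert header[:3] == ["id", "name", "reference_rt_min"]
    for line in lines[1:]:
        pid, name, rt, w1, w2, w3 = line.split("\t")
        compounds.append(
            PigmentCompound(int(pid), name, float(rt), (float(w1), float(w2), float(w3)))
        )
    return PigmentLibrary(compounds)


def load_profiles() -> dict[str, SpeciesPigmentProfile]:
    """Load the fifteen encoded reference species profiles."""
    lines = _data_text("profiles.tsv").strip().splitlines()
    header = lines[0].split("\t")
    assert header[0] == "species" and header[1:16] == [f"p{i}" for i in PIGMENT_IDS]
    profiles: dict[str, SpeciesPigmentProfile] = {}
    for line in lines[1:]:
        fields = line.split("\t")
        species = fields[0]
        levels = {
            pid: lvl
            for pid, lvl in zip(PIGMENT_IDS, fields[1:16])
            if lvl in ("trace", "main")
        }
        unknown = [float(x) for x in fields[16].split(",")] if len(fields) > 16 and fields[16] else []
        profiles[species] = SpeciesPigmentProfile(species, levels, unknown_peaks=unknown)
    return profiles


def load_groups() -> list[PigmentGroup]:
    """Load the four pigment groups with their constraint rules."""
    raw = json.loads(_data_text("groups.json"))["groups"]
    groups = [
        PigmentGroup(
            name=g["name"],
            required=frozenset(g["required"]),
            forbidden=frozenset(g["forbidden"]),
            any_of=tuple(frozenset(a) for a in g["any_of"]),
            members=tuple(g["members"]),
        )
        for g in raw
    ]
    all_members = [m for g in groups for m in g.members]
    if len(all_members) != len(set(all_members)):
        raise ValueError("curated group member lists are not disjoint")
    return groups


def load_reference() -> tuple[PigmentLibrary, dict[str, SpeciesPigmentProfile], list[PigmentGroup]]:
    """Load library, species profiles and groups, cross-validated against each other."""
    library = load_library()
    profiles = load_profiles()
    groups = load_groups()
    for p in profiles.values():
        unknown_ids = p.present - set(library.ids)
        if unknown_ids:
            raise ValueError(f"profile {p.species} references unknown pigments {unknown_ids}")
    for g in groups:
        missing = set(g.members) - set(profiles)
        if missing:
            raise ValueError(f"group {g.name} lists unknown species {missing}")
    return library, profiles, groups


def profile_distance(p: SpeciesPigmentProfile, q: SpeciesPigmentProfile) -> float:
    """Bray-Curtis dissimilarity between two profiles' weight vectors, in [0, 1].

    Measured relative quantities are used when *both* profiles carry them;
    otherwise both profiles are compared on the common level-weight scale so
    that measured and encoded profiles remain commensurable.
    """
    use_q = p.quantities is not None and q.quantities is not None
    x, y = p.weight_vector(use_q), q.weight_vector(use_q)
    total = x.sum() + y.sum()
    if total == 0:
        raise ValueError("Bray-Curtis undefined for two empty profiles")
    return float(1.0 - 2.0 * np.minimum(x, y).sum() / total)


def group_centroid(group: PigmentGroup, profiles: dict[str, SpeciesPigmentProfile]) -> np.ndarray:
    """Mean level-weight vector of the group's curated members."""
    return np.mean(
        [profiles[m].weight_vector(use_quantities=False) for m in group.members], axis=0
    )


def assign_group(
    profile: SpeciesPigmentProfile,
    groups: list[PigmentGroup],
    profiles: dict[str, SpeciesPigmentProfile],
) -> tuple[str, float] | None:
    """Assign a profile to a pigment group.

    Stage 1 keeps groups whose constraint rule admits the profile; stage 2
    picks, among survivors, the group with the nearest centroid (Bray-Curtis
    on the level-weight scale, since centroids are built from encoded
    profiles).  Returns ``None`` (unassigned) when the profile is empty or no
    group's constraints are met.
    """
    if not profile.present:
        return None
    survivors = [g for g in groups if g.admits(profile)]
    if not survivors:
        return None
    x = profile.weight_vector(use_quantities=False)
    best_name, best_d = None, np.inf
    for g in sorted(survivors, key=lambda g: g.name):
        c = group_centroid(g, profiles)
        total = x.sum() + c.sum()
        d = 1.0 - 2.0 * np.minimum(x, c).sum() / total
        if d < best_d:
            best_name, best_d = g.name, d
    return best_name, float(best_d)


def match_species(
    query: SpeciesPigmentProfile, references: dict[str, SpeciesPigmentProfile]
) -> list[tuple[str, float]]:
    """Rank all reference species by ascending profile distance to the query.

    Ties are broken alphabetically.  Supports re-identification of herbarium
    material from its pigment profile alone.
    """
    ranked = [(sp, profile_distance(query, ref)) for sp, ref in references.items()]
    ranked.sort(key=lambda t: (t[1], t[0]))
    return ranked
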