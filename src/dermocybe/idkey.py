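"""Dichotomous identification key: encoding, validation and traversal.

The packaged key covers the *Dermocybe* species of Central European
coniferous forests: 28 couplets whose 28 terminal leads resolve 26 distinct
taxa (two taxa each terminate two leads, reflecting alternative character
routes in the printed key).  Lead predicates are conjunctions over a
controlled character vocabulary - categorical states (colours, hosts, KOH
reactions, UV fluorescence) and numeric thresholds (mean spore dimensions in
micrometres).

Traversal uses candidate-set semantics: a lead whose predicate cannot be
evaluated because of unknown character states is followed alongside any
satisfied lead, so partial field observations narrow the answer to a set of
taxa instead of failing.  A record that contradicts both leads of a couplet
blocks that branch, and the blocking couplet is reported.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping

Record = Mapping[str, object]  # character name -> state (str) or value (float)


@dataclass(frozen=True)
class Condition:
    """One character-state (or numeric threshold) condition."""

    character: str
    states: frozenset[str] | None = None
    op: str | None = None  # "lt" | "gt"
    value: float | None = None

    def evaluate(self, record: Record) -> bool | None:
        """True/False when decidable from the record, None when unknown."""
        if self.character not in record or record[self.character] is None:
            return None
        observed = record[self.character]
        if self.states is not None:
            return str(observed) in self.states
        x = float(observed)  # numeric threshold condition
        return x < self.value if self.op == "lt" else x > self.value


@dataclass(frozen=True)
class Lead:
    """One of a couplet's two alternatives."""

    couplet: str
    index: int  # 0 = first lead, 1 = second ("starred") lead
    text: str
    conditions: tuple[Condition, ...]
    next_couplet: str | None = None
    taxon: str | None = None
    asterisk: bool = False
    qualifier: str | None = None

    def __post_init__(self) -> None:
        if (self.next_couplet is None) == (self.taxon is None):
            raise ValueError(
                f"lead {self.couplet}/{self.index}: outcome must be exactly one "
                "of next couplet or terminal taxon"
            )

    @property
    def is_terminal(self) -> bool:
        return self.taxon is not None

    def status(self, record: Record) -> str:
        """'satisfied', 'contradicted' or 'undecided' for a record."""
        results = [c.evaluate(record) for c in self.conditions]
        if any(r is False for r in results):
            return "contradicted"
        if all(r is True for r in results):
            return "satisfied"
        return "undecided"


@dataclass
class IdentificationKey:
    couplets: dict[str, tuple[Lead, Lead]]
    entry: str
    characters: dict[str, dict]
    metadata: dict = field(default_factory=dict)

    def terminal_leads(self) -> list[Lead]:
        return [l for pair in self.couplets.values() for l in pair if l.is_terminal]

    def taxa(self) -> list[str]:
        return sorted({l.taxon for l in self.terminal_leads()})


def load_key() -> IdentificationKey:
    """Load the packaged key fixture."""
    raw = json.loads(
        resources.files("dermocybe.data").joinpath("key.json").read_text(encoding="utf-8")
    )
    couplets: dict[str, tuple[Lead, Lead]] = {}
    for cid, leads in raw["couplets"].items():
        if len(leads) != 2:
            raise ValueError(f"couplet {cid} does not have exactly two leads")
        parsed = []
        for i, lead in enumerate(leads):
            conditions = []
            for cond in lead.get("conditions", []):
                if cond["character"] not in raw["characters"]:
                    raise ValueError(
                        f"couplet {cid}: unknown character {cond['character']!r}"
                    )
                if "states" in cond:
                    known = set(raw["characters"][cond["character"]]["states"])
                    bad = set(cond["states"]) - known
                    if bad:
                        raise ValueError(
                            f"couplet {cid}: states {bad} not in vocabulary of "
                            f"{cond['character']!r}"
                        )
                    conditions.append(
                        Condition(cond["character"], states=frozenset(cond["states"]))
                    )
                else:
                    if cond["op"] not in ("lt", "gt"):
                        raise ValueError(f"couplet {cid}: bad numeric op {cond['op']!r}")
                    conditions.append(
                        Condition(cond["character"], op=cond["op"], value=float(cond["value"]))
                    )
            parsed.append(
                Lead(
                    couplet=cid,
                    index=i,
                    text=lead.get("text", ""),
                    conditions=tuple(conditions),
                    next_couplet=lead.get("next"),
                    taxon=lead.get("taxon"),
                    asterisk=bool(lead.get("asterisk", False)),
                    qualifier=lead.get("qualifier"),
                )
            )
        couplets[cid] = (parsed[0], parsed[1])
    return IdentificationKey(
        couplets=couplets,
        entry=raw["metadata"]["entry"],
        characters=raw["characters"],
        metadata=raw["metadata"],
    )


def validate_key(key: IdentificationKey) -> dict:
    """Structural validation report: binarity, acyclicity, reachability,
    dangling references and twin-lead redundancy.  Never raises; violations
    are listed in the report."""
    violations: list[str] = []
    for cid, pair in key.couplets.items():
        if len(pair) != 2:
            violations.append(f"couplet {cid}: not exactly two leads")
        a, b = pair
        if (
            a.conditions == b.conditions
            and a.conditions  # two unconditioned leads are vacuously 'identical'
        ) or (not a.conditions and not b.conditions):
            violations.append(f"couplet {cid}: leads have identical predicates")
        for lead in pair:
            if lead.next_couplet is not None and lead.next_couplet not in key.couplets:
                violations.append(
                    f"couplet {cid}: dangling reference to couplet {lead.next_couplet}"
                )
    if key.entry not in key.couplets:
        violations.append(f"entry couplet {key.entry} missing")
        return {"violations": violations, "valid": False}
    # cycle detection (DFS colouring) over the couplet graph
    WHITE, GREY, BLACK = 0, 1, 2
    colour = {cid: WHITE for cid in key.couplets}

    def dfs(cid: str) -> None:
        colour[cid] = GREY
        for lead in key.couplets[cid]:
            nxt = lead.next_couplet
            if nxt is None or nxt not in key.couplets:
                continue
            if colour[nxt] == GREY:
                violations.append(f"cycle through couplet {nxt}")
            elif colour[nxt] == WHITE:
                dfs(nxt)
        colour[cid] = BLACK

    dfs(key.entry)
    unreachable = [cid for cid, c in colour.items() if c == WHITE]
    for cid in sorted(unreachable, key=lambda s: (len(s), s)):
        violations.append(f"couplet {cid} unreachable from entry")
    return {"violations": violations, "valid": not violations}


@dataclass
class TraversalResult:
    """Outcome of identifying a specimen record against the key."""

    taxa: list[str]
    paths: dict[str, list[str]]  # representative couplet path per taxon
    blocked_couplets: list[str]
    leads: list[Lead] = field(default_factory=list)

    @property
    def determinate(self) -> bool:
        return len(self.taxa) == 1


def identify(key: IdentificationKey, record: Record) -> TraversalResult:
    """Traverse the key with a (possibly partial) character-state record.

    At each couplet the traversal follows every lead that is satisfied or
    undecidable; fully known records follow a single path, partial records
    yield the set of taxa compatible with the observations.  A couplet whose
    two leads are both contradicted blocks its branch and is reported.
    """
    taxa: dict[str, list[str]] = {}
    leads: list[Lead] = []
    blocked: list[str] = []

    def walk(cid: str, path: list[str]) -> None:
        pair = key.couplets[cid]
        statuses = [l.status(record) for l in pair]
        followed = [
            l for l, s in zip(pair, statuses) if s in ("satisfied", "undecided")
        ]
        if not followed:
            blocked.append(cid)
            return
        for lead in followed:
            if lead.is_terminal:
                if lead.taxon not in taxa:
                    taxa[lead.taxon] = path + [cid]
                    leads.append(lead)
            else:
                walk(lead.next_couplet, path + [cid])

    walk(key.entry, [])
    return TraversalResult(
        taxa=sorted(taxa),
        paths=taxa,
        blocked_couplets=blocked,
        leads=leads,
    )


def _bfs_parents(key: IdentificationKey) -> tuple[list[str], dict[str, tuple[str, Lead]]]:
    """Breadth-first discovery order of couplets and the discovering edge.

    The lead graph may be a DAG (one couplet reachable along several routes,
    as in the printed key); the shortest route found first is canonical.
    """
    order: list[str] = [key.entry]
    parents: dict[str, tuple[str, Lead]] = {}
    frontier = [key.entry]
    seen = {key.entry}
    while frontier:
        nxt: list[str] = []
        for cid in frontier:
            for lead in key.couplets[cid]:
                target = lead.next_couplet
                if target is not None and target not in seen:
                    seen.add(target)
                    parents[target] = (cid, lead)
                    order.append(target)
                    nxt.append(target)
        frontier = nxt
    return order, parents


def _canonical_path_to(key: IdentificationKey, cid: str,
                       parents: dict[str, tuple[str, Lead]]) -> list[tuple[str, Lead]]:
    path: list[tuple[str, Lead]] = []
    while cid != key.entry:
        parent_cid, lead = parents[cid]
        path.append((parent_cid, lead))
        cid = parent_cid
    path.reverse()
    return path


def lead_paths(key: IdentificationKey) -> list[list[tuple[str, Lead]]]:
    """Canonical root-to-terminal path per terminal lead (28 in the packaged key)."""
    order, parents = _bfs_parents(key)
    out: list[list[tuple[str, Lead]]] = []
    for cid in order:
        prefix = _canonical_path_to(key, cid, parents)
        for lead in key.couplets[cid]:
            if lead.is_terminal:
                out.append(prefix + [(cid, lead)])
    return out


def _canonical_paths(key: IdentificationKey) -> dict[str, list[tuple[str, Lead]]]:
    """Canonical path to each distinct terminal taxon (first lead in BFS order)."""
    paths: dict[str, list[tuple[str, Lead]]] = {}
    for path in lead_paths(key):
        paths.setdefault(path[-1][1].taxon, path)
    return paths


def record_for_path(path: list[tuple[str, Lead]]) -> dict[str, object]:
    """Conjoin all predicates along a key path into a concrete record.

    Categorical conditions on the same character are intersected and a single
    representative state chosen; numeric thresholds pick a value 1 µm beyond
    the strictest bound.  Used for round-trip identifiability checks and for
    generating exemplar records per taxon.
    """
    state_sets: dict[str, set[str]] = {}
    bounds: dict[str, list[float]] = {}  # [lower, upper]
    for _, lead in path:
        for cond in lead.conditions:
            if cond.states is not None:
                cur = state_sets.setdefault(cond.character, set(cond.states))
                cur &= cond.states
                if not cur:
                    raise ValueError(
                        f"inconsistent categorical conditions on {cond.character!r} "
                        "along path"
                    )
                state_sets[cond.character] = cur
            else:
                lo, hi = bounds.setdefault(cond.character, [-math.inf, math.inf])
                if cond.op == "gt":
                    bounds[cond.character][0] = max(lo, cond.value)
                else:
                    bounds[cond.character][1] = min(hi, cond.value)
    record: dict[str, object] = {}
    for char, states in state_sets.items():
        record[char] = sorted(states)[0]
    for char, (lo, hi) in bounds.items():
        if lo >= hi:
            raise ValueError(f"inconsistent numeric conditions on {char!r} along path")
        if math.isinf(lo):
            record[char] = hi - 1.0
        elif math.isinf(hi):
            record[char] = lo + 1.0
        else:
            record[char] = (lo + hi) / 2.0
    return record


def distinguishing_characters(
    key: IdentificationKey, taxon_a: str, taxon_b: str
) -> list[str]:
    """Characters separating two terminal taxa.

    Collects the characters used by the predicates along the canonical paths
    from the deepest shared couplet down to each taxon.  An empty list for a
    taxon compared with itself.
    """
    paths = _canonical_paths(key)
    for t in (taxon_a, taxon_b):
        if t not in paths:
            raise ValueError(f"unknown terminal taxon {t!r}")
    if taxon_a == taxon_b:
        return []
    pa, pb = paths[taxon_a], paths[taxon_b]
    shared = 0
    for (ca, la), (cb, lb) in zip(pa, pb):
        if ca == cb and la.index == lb.index:
            shared += 1
        else:
            break
    chars: list[str] = []
    for _, lead in pa[shared:] + pb[shared:]:
        for cond in lead.conditions:
            if cond.character not in chars:
                chars.append(cond.character)
    return chars
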