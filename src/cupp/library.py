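"""Finalized peptide group models and the cross-family lookup library.

A finalized group stores each conserved peptide with a weight equal to the
*square* of its within-group conservation fraction (so a peptide present in
90% of members scores 0.81 per hit while one present in 21% scores only
0.044) after dropping peptides not strictly above the 20% retention floor.

Group models from all families are then compiled into one inverted index.
Peptides occurring in several families have their weights divided by the
number of families involved, and peptides consisting solely of the abundant
aliphatic residues or proline are banned outright to avoid bias toward
linkers and polyproline stretches.
"""

from __future__ import annotations

import json
import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

from .clustering import ProvisionalGroup
from .family_io import ProteinMeta
from .peptides import PeptideParams, PeptidePool, WILDCARD

logger = logging.getLogger(__name__)

FORMAT_VERSION = 1

#: Residues whose exclusive presence bans a peptide from the library:
#: the abundant aliphatics plus proline.
BANNED_RESIDUES = frozenset("GAVLIP")


def conservation_weight(conservation: float) -> float:
    """Weight stored for a conserved peptide: the squared conservation.

    Squaring favors the more conserved peptides: 0.9 -> 0.81 while
    0.2 -> 0.04.
    """
    if not 0.0 <= conservation <= 1.0:
        raise ValueError(f"conservation must lie in [0, 1], got {conservation}")
    return conservation * conservation


def is_banned(peptide: str) -> bool:
    """True iff every non-wildcard residue is aliphatic (GAVLI) or proline."""
    return all(c in BANNED_RESIDUES for c in peptide if c != WILDCARD)


def summarize_metadata(metas: list[ProteinMeta]) -> dict:
    """Count subfamily, EC and taxonomy evidence across member metadata."""
    sub = Counter(m.subfamily for m in metas if m.subfamily is not None)
    ec = Counter(tok for m in metas for tok in m.ec_functions)
    tax = Counter(m.taxonomy_class for m in metas if m.taxonomy_class)
    return {
        "n_meta": len(metas),
        "subfamily": {str(k): v for k, v in sorted(sub.items())},
        "ec": dict(sorted(ec.items())),
        "taxonomy": dict(sorted(tax.items())),
    }


@dataclass
class CuppGroup:
    """A finalized group: weighted peptides plus member evidence."""

    label: str  # family-qualified, e.g. "GH30:1"
    peptides: dict[str, float]  # peptide -> weight (squared conservation)
    members: tuple[str, ...]
    meta_summary: dict
    avg_covered_positions: float

    @property
    def family(self) -> str:
        return self.label.split(":")[0]

    @property
    def theoretical_max(self) -> float:
        return sum(self.peptides.values())


def finalize_group(
    provisional: ProvisionalGroup,
    pools: dict[str, PeptidePool],
    metas: dict[str, list[ProteinMeta]],
    label: str,
    peptide_params: PeptideParams,
    retain: float = 0.20,
) -> CuppGroup | None:
    """Turn a provisional group into a weighted peptide model.

    Peptides whose conservation is not strictly above ``retain`` are
    dropped; surviving conservations are squared into weights.  The
    average covered-position count per member (used later to bridge gaps
    during range inference) is computed under the retained peptides.
    Returns None (with a warning) for a group left without any peptide.
    """
    retained = {
        pep: conservation_weight(c)
        for pep, c in provisional.conserved.items()
        if c > retain
    }
    if not retained:
        logger.warning(
            "group %s discarded: no peptide above the %.0f%% retention floor",
            label,
            retain * 100,
        )
        return None
    n = peptide_params.n
    covered_counts = []
    for pid in provisional.member_ids:
        pool = pools[pid]
        covered: set[int] = set()
        for pep in retained:
            for s in pool.entries.get(pep, ()):
                covered.update(range(s, s + n))
        covered_counts.append(len(covered))
    member_metas = [m for pid in provisional.member_ids for m in metas.get(pid, [])]
    return CuppGroup(
        label=label,
        peptides=retained,
        members=provisional.member_ids,
        meta_summary=summarize_metadata(member_metas),
        avg_covered_positions=sum(covered_counts) / len(covered_counts),
    )


@dataclass
class GroupSummary:
    """Per-group information the predictor needs, post weight adjustment."""

    label: str
    theoretical_max: float
    avg_covered_positions: float
    meta_summary: dict
    n_members: int

    @property
    def family(self) -> str:
        return self.label.split(":")[0]


@dataclass
class CuppLibrary:
    """Inverted peptide index across all families plus group summaries."""

    params: PeptideParams
    index: dict[str, list[tuple[str, float]]] = field(default_factory=dict)
    groups: dict[str, GroupSummary] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.index)


def compile_library(
    groups: list[CuppGroup], params: PeptideParams
) -> CuppLibrary:
    """Merge finalized groups from any number of families into one index.

    For every peptide the number of distinct families among its owning
    groups is counted and each weight divided by that count; banned
    peptides are removed; per-group theoretical maxima are recomputed on
    the adjusted weights.
    """
    labels = [g.label for g in groups]
    dups = sorted({lab for lab in labels if labels.count(lab) > 1})
    if dups:
        raise ValueError(f"duplicate group labels {dups}")
    families_of: dict[str, set[str]] = {}
    for g in groups:
        for pep in g.peptides:
            if is_banned(pep):
                continue
            families_of.setdefault(pep, set()).add(g.family)
    index: dict[str, list[tuple[str, float]]] = {}
    adjusted_max: dict[str, float] = {g.label: 0.0 for g in groups}
    for g in sorted(groups, key=lambda g: g.label):
        for pep, weight in g.peptides.items():
            if pep not in families_of:
                continue
            adj = weight / len(families_of[pep])
            index.setdefault(pep, []).append((g.label, adj))
            adjusted_max[g.label] += adj
    summaries = {
        g.label: GroupSummary(
            label=g.label,
            theoretical_max=adjusted_max[g.label],
            avg_covered_positions=g.avg_covered_positions,
            meta_summary=g.meta_summary,
            n_members=len(g.members),
        )
        for g in groups
    }
    return CuppLibrary(params=params, index=index, groups=summaries)


def group_label(family: str, number: int) -> str:
    return f"{family}:{number}"


def finalize_family(
    result,
    metas: dict[str, list[ProteinMeta]],
    family: str,
    retain: float = 0.20,
) -> list[CuppGroup]:
    """Finalize every group of a clustering result under family labels.

    Groups are numbered 1..k in order of smallest member id, matching the
    deterministic ordering of the clustering engine.
    """
    out: list[CuppGroup] = []
    number = 0
    for provisional in result.groups:
        number += 1
        g = finalize_group(
            provisional,
            result.final_pools,
            metas,
            group_label(family, number),
            result.params.peptide_params,
            retain=retain,
        )
        if g is not None:
            out.append(g)
    return out


# ---------------------------------------------------------------------------
# Serialization: single self-describing JSON archives


def save_groups(
    groups: list[CuppGroup], params: PeptideParams, path: str | Path
) -> None:
    """Write finalized groups of one clustering run (pre-compilation)."""
    doc = {
        "format": "cupp-groups",
        "version": FORMAT_VERSION,
        "params": {"n": params.n, "a": params.a},
        "groups": [
            {
                "label": g.label,
                "peptides": dict(sorted(g.peptides.items())),
                "members": list(g.members),
                "meta_summary": g.meta_summary,
                "avg_covered_positions": g.avg_covered_positions,
            }
            for g in sorted(groups, key=lambda g: g.label)
        ],
    }
    with open(path, "w") as out:
        json.dump(doc, out, separators=(",", ":"))


def load_groups(path: str | Path) -> tuple[list[CuppGroup], PeptideParams]:
    try:
        with open(path) as handle:
            doc = json.load(handle)
    except json.JSONDecodeError as exc:
        raise ValueError(f"{path}: corrupt or truncated group archive") from exc
    if doc.get("format") != "cupp-groups" or doc.get("version") != FORMAT_VERSION:
        raise ValueError(f"{path}: not a supported group archive")
    params = PeptideParams(doc["params"]["n"], doc["params"]["a"])
    groups = [
        CuppGroup(
            label=g["label"],
            peptides=g["peptides"],
            members=tuple(g["members"]),
            meta_summary=g["meta_summary"],
            avg_covered_positions=g["avg_covered_positions"],
        )
        for g in doc["groups"]
    ]
    return groups, params


def save_library(lib: CuppLibrary, path: str | Path) -> None:
    doc = {
        "format": "cupp-library",
        "version": FORMAT_VERSION,
        "params": {"n": lib.params.n, "a": lib.params.a},
        "groups": {
            lab: {
                "theoretical_max": s.theoretical_max,
                "avg_covered_positions": s.avg_covered_positions,
                "meta_summary": s.meta_summary,
                "n_members": s.n_members,
            }
            for lab, s in sorted(lib.groups.items())
        },
        "index": {
            pep: [[lab, w] for lab, w in hits]
            for pep, hits in sorted(lib.index.items())
        },
    }
    with open(path, "w") as out:
        json.dump(doc, out, separators=(",", ":"))


def load_library(path: str | Path) -> CuppLibrary:
    try:
        with open(path) as handle:
            doc = json.load(handle)
    except json.JSONDecodeError as exc:
        raise ValueError(f"{path}: corrupt or truncated library archive") from exc
    if doc.get("format") != "cupp-library":
        raise ValueError(f"{path}: not a peptide library archive")
    if doc.get("version") != FORMAT_VERSION:
        raise ValueError(
            f"{path}: library format version {doc.get('version')} "
            f"not supported (expected {FORMAT_VERSION})"
        )
    params = PeptideParams(doc["params"]["n"], doc["params"]["a"])
    groups = {
        lab: GroupSummary(
            label=lab,
            theoretical_max=g["theoretical_max"],
            avg_covered_positions=g["avg_covered_positions"],
            meta_summary=g["meta_summary"],
            n_members=g["n_members"],
        )
        for lab, g in doc["groups"].items()
    }
    index = {
        pep: [(lab, w) for lab, w in hits] for pep, hits in doc["index"].items()
    }
    return CuppLibrary(params=params, index=index, groups=groups)
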