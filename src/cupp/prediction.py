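"""Annotation of query proteins against a peptide library.

A query is windowed and expanded exactly like a training sequence; every
variant hit in the library index is recorded per group.  Candidate groups
then pass a cascade of filters:

1. *initial filter* — the sum of matched peptide weights (each peptide
   counted once) must be at least 5 and at least 1% of the group's
   theoretical maximum;
2. *position filter* (full mode) — at least 20 residue positions of the
   accumulated-weight profile must exceed 0.2, the minimum domain length;
3. *overlap resolution* (full mode) — groups are processed in decreasing
   fraction-of-maximum order; a later group survives only if at least 50%
   of its accumulation mass lies outside already-claimed positions;
4. *assignment* — a surviving group is reported when it reaches 5% of its
   theoretical maximum, together with subfamily (requires >= 3 members of
   one subfamily) and the most abundant member EC function; weaker hits
   fall back to the family-only ``FAM.0.1`` sentinel.

Fast mode skips steps 2–4, requires matched peptides at eight or more
distinct query start positions, and reports the family-level ``FAM.0.0``
sentinel only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .family_io import ANNOTATION_COLUMNS
from .library import CuppLibrary
from .peptides import STANDARD_RESIDUES, expand_variants

logger = logging.getLogger(__name__)

SUM_FLOOR = 5.0
FRAC_FLOOR = 0.01
ASSIGN_FRAC = 0.05
MIN_DOMAIN_LENGTH = 20
ACCUMULATION_FLOOR = 0.2
FAST_MIN_POSITIONS = 8
UNOCCUPIED_MASS_FRAC = 0.5
GAP_MIN, GAP_MAX = 50, 200
SUBFAMILY_MIN_MEMBERS = 3


@dataclass
class MatchProfile:
    """All matches of one query against one library group."""

    label: str
    query_length: int
    window_n: int
    # peptide -> (adjusted weight, sorted query start positions)
    matches: dict[str, tuple[float, tuple[int, ...]]] = field(default_factory=dict)

    @property
    def sum_unique(self) -> float:
        """Sum of matched weights, each peptide counted once."""
        return sum(w for w, _ in self.matches.values())

    @property
    def start_positions(self) -> set[int]:
        out: set[int] = set()
        for _, starts in self.matches.values():
            out.update(starts)
        return out

    def accumulation(self) -> np.ndarray:
        """Per-residue sum of covering peptide weights, repeats counted."""
        acc = np.zeros(self.query_length)
        for w, starts in self.matches.values():
            for s in starts:
                acc[s : s + self.window_n] += w
        return acc


@dataclass
class DomainCall:
    label: str  # internal group label ("GH30:1") or a sentinel
    family: str
    ranges: list[tuple[int, int]]
    score: float
    frac_of_max: float
    subfamily: int | None = None
    ec: str | None = None

    @property
    def report_label(self) -> str:
        """Dotted report form: ``GH30.1.1`` for group 1, sentinels as-is."""
        if ":" in self.label:
            fam, num = self.label.split(":")
            return f"{fam}.{num}.1"
        return self.label


@dataclass
class Annotation:
    query_id: str
    mode: str
    calls: list[DomainCall] = field(default_factory=list)

    def rows(self) -> list[dict]:
        rows = []
        for call in self.calls:
            rows.append(
                {
                    "query_id": self.query_id,
                    "family": call.family,
                    "group_label": call.report_label,
                    "ranges": ";".join(f"{s}.{e}" for s, e in call.ranges),
                    "score": f"{call.score:.3f}",
                    "frac_of_max": f"{call.frac_of_max:.4f}",
                    "subfamily": "" if call.subfamily is None else call.subfamily,
                    "ec": call.ec or "",
                    "mode": self.mode,
                }
            )
        assert all(set(r) == set(ANNOTATION_COLUMNS) for r in rows)
        return rows

    @property
    def families(self) -> set[str]:
        return {c.family for c in self.calls}


# ---------------------------------------------------------------------------
# Steps


def lookup(sequence: str, lib: CuppLibrary) -> dict[str, MatchProfile]:
    """Record every library hit of the query's peptide variants, per group."""
    seq = sequence.upper()
    n, a = lib.params.n, lib.params.a
    profiles: dict[str, MatchProfile] = {}
    if len(seq) < n:
        logger.warning("query shorter than window (%d < %d); no matches", len(seq), n)
        return profiles
    hits: dict[str, list[int]] = {}  # peptide -> query starts
    ok = [c in STANDARD_RESIDUES for c in seq]
    bad_in_window = sum(not v for v in ok[:n])
    for s in range(len(seq) - n + 1):
        if s > 0:
            bad_in_window += (not ok[s + n - 1]) - (not ok[s - 1])
        if bad_in_window:
            continue
        for variant in expand_variants(seq[s : s + n], a):
            if variant in lib.index:
                hits.setdefault(variant, []).append(s)
    for pep, starts in hits.items():
        starts_t = tuple(sorted(set(starts)))
        for label, weight in lib.index[pep]:
            prof = profiles.get(label)
            if prof is None:
                prof = profiles[label] = MatchProfile(
                    label=label, query_length=len(seq), window_n=n
                )
            prof.matches[pep] = (weight, starts_t)
    return profiles


def initial_filter(
    profiles: dict[str, MatchProfile], lib: CuppLibrary, mode: str = "full"
) -> list[MatchProfile]:
    """Keep groups passing the weight-sum and fraction-of-maximum floors."""
    kept = []
    for label in sorted(profiles):
        prof = profiles[label]
        tmax = lib.groups[label].theoretical_max
        s = prof.sum_unique
        if s < SUM_FLOOR or tmax <= 0 or s < FRAC_FLOOR * tmax:
            continue
        if mode == "fast" and len(prof.start_positions) < FAST_MIN_POSITIONS:
            continue
        kept.append(prof)
    return kept


def position_filter(profile: MatchProfile) -> bool:
    """Require a minimum-domain-length stretch of confident accumulation."""
    acc = profile.accumulation()
    return int((acc > ACCUMULATION_FLOOR).sum()) >= MIN_DOMAIN_LENGTH


def resolve_overlaps(
    profiles: list[MatchProfile], lib: CuppLibrary
) -> list[tuple[MatchProfile, float]]:
    """Greedy occupancy resolution among passing profiles.

    Profiles are processed in decreasing fraction of their group's
    theoretical maximum.  The first claims its covered positions; a later
    profile is kept only if at least half of its accumulation mass falls
    on unclaimed positions.  Returns (profile, frac_of_max) pairs in
    processing order.
    """
    scored = []
    for prof in profiles:
        tmax = lib.groups[prof.label].theoretical_max
        frac = prof.sum_unique / tmax if tmax > 0 else 0.0
        scored.append((prof, frac))
    scored.sort(key=lambda pf: (-pf[1], pf[0].label))
    occupied: np.ndarray | None = None
    kept: list[tuple[MatchProfile, float]] = []
    for prof, frac in scored:
        acc = prof.accumulation()
        covered = acc > 0
        if occupied is None:
            occupied = covered.copy()
            kept.append((prof, frac))
            continue
        total = float(acc.sum())
        outside = float(acc[~occupied].sum())
        if total > 0 and outside >= UNOCCUPIED_MASS_FRAC * total:
            occupied |= covered
            kept.append((prof, frac))
    return kept


def infer_ranges(profile: MatchProfile, avg_covered_positions: float) -> list[
    tuple[int, int]
]:
    """Merge covered positions into domain ranges.

    Gaps no larger than the group's average covered-position count
    (clamped to 50–200 residues) are bridged; larger gaps split the call
    into separate ranges, which keeps tandem repeats of one domain apart.
    """
    acc = profile.accumulation()
    covered = np.flatnonzero(acc > 0)
    if covered.size == 0:
        return []
    gap_limit = int(min(max(avg_covered_positions, GAP_MIN), GAP_MAX))
    ranges: list[tuple[int, int]] = []
    run_start = prev = int(covered[0])
    for pos in covered[1:]:
        pos = int(pos)
        if pos - prev - 1 > gap_limit:
            ranges.append((run_start, prev + 1))
            run_start = pos
        prev = pos
    ranges.append((run_start, prev + 1))
    return ranges


def _modal_subfamily(meta_summary: dict) -> int | None:
    counts = meta_summary.get("subfamily", {})
    best = None
    for sub, c in counts.items():
        if c >= SUBFAMILY_MIN_MEMBERS and (best is None or c > best[1]):
            best = (int(sub), c)
    return best[0] if best else None


def _ec_string(meta_summary: dict) -> str | None:
    """Most abundant member EC first; rarer functions joined by '-'."""
    counts = meta_summary.get("ec", {})
    if not counts:
        return None
    ordered = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return "-".join(tok for tok, _ in ordered)


def _overlap(a: tuple[int, int], b: tuple[int, int]) -> int:
    return max(0, min(a[1], b[1]) - max(a[0], b[0]))


def _ranges_coincide(ra: list[tuple[int, int]], rb: list[tuple[int, int]]) -> bool:
    """True when two calls sit on the same region of the query."""
    shorter = min(
        sum(e - s for s, e in ra),
        sum(e - s for s, e in rb),
    )
    if shorter == 0:
        return False
    overlap = sum(_overlap(x, y) for x in ra for y in rb)
    return overlap >= 0.5 * shorter


def assign(
    kept: list[tuple[MatchProfile, float]], lib: CuppLibrary, query_id: str, mode: str
) -> Annotation:
    """Turn resolved profiles into the final annotation."""
    ann = Annotation(query_id=query_id, mode=mode)
    calls: list[DomainCall] = []
    for prof, frac in kept:
        summary = lib.groups[prof.label]
        ranges = infer_ranges(prof, summary.avg_covered_positions)
        if frac >= ASSIGN_FRAC:
            calls.append(
                DomainCall(
                    label=prof.label,
                    family=summary.family,
                    ranges=ranges,
                    score=prof.sum_unique,
                    frac_of_max=frac,
                    subfamily=_modal_subfamily(summary.meta_summary),
                    ec=_ec_string(summary.meta_summary),
                )
            )
        else:
            calls.append(
                DomainCall(
                    label=f"{summary.family}.0.1",
                    family=summary.family,
                    ranges=ranges,
                    score=prof.sum_unique,
                    frac_of_max=frac,
                )
            )
    # two groups of one family on the same range collapse to FAM.0.2
    merged: list[DomainCall] = []
    for call in calls:
        clashing = next(
            (
                c
                for c in merged
                if c.family == call.family
                and ":" in c.label
                and ":" in call.label
                and _ranges_coincide(c.ranges, call.ranges)
            ),
            None,
        )
        if clashing is not None:
            idx = merged.index(clashing)
            merged[idx] = DomainCall(
                label=f"{call.family}.0.2",
                family=call.family,
                ranges=clashing.ranges,
                score=clashing.score,
                frac_of_max=clashing.frac_of_max,
            )
        else:
            merged.append(call)
    ann.calls = merged
    return ann


def annotate(
    query_id: str, sequence: str, lib: CuppLibrary, mode: str = "full"
) -> Annotation:
    """Annotate a single query sequence. ``mode`` is "full" or "fast"."""
    if mode not in ("full", "fast"):
        raise ValueError(f"unknown prediction mode {mode!r}")
    profiles = lookup(sequence, lib)
    candidates = initial_filter(profiles, lib, mode)
    if mode == "fast":
        ann = Annotation(query_id=query_id, mode=mode)
        best_per_family: dict[str, MatchProfile] = {}
        for prof in candidates:
            fam = lib.groups[prof.label].family
            cur = best_per_family.get(fam)
            if cur is None or prof.sum_unique > cur.sum_unique:
                best_per_family[fam] = prof
        for fam in sorted(best_per_family):
            prof = best_per_family[fam]
            tmax = lib.groups[prof.label].theoretical_max
            ann.calls.append(
                DomainCall(
                    label=f"{fam}.0.0",
                    family=fam,
                    ranges=[],
                    score=prof.sum_unique,
                    frac_of_max=prof.sum_unique / tmax if tmax > 0 else 0.0,
                )
            )
        return ann
    passing = [p for p in candidates if position_filter(p)]
    if not passing:
        return Annotation(query_id=query_id, mode=mode)
    kept = resolve_overlaps(passing, lib)
    return assign(kept, lib, query_id, mode)


def annotate_many(
    queries: list[tuple[str, str]], lib: CuppLibrary, mode: str = "full"
) -> list[Annotation]:
    """Annotate queries against a single upfront-loaded library."""
    return [annotate(qid, seq, lib, mode) for qid, seq in queries]
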