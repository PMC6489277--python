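"""Readers and writers for every external artifact.

Formats handled here: FASTA (plain or gzip), per-protein metadata TSV,
domain-range TSV, CD-HIT ``.clstr`` cluster files, annotation TSV, and
Newick export of linkage trees.  The peptide-library archive has its own
reader/writer in :mod:`cupp.library`.

Metadata TSV schema (tab-separated, header required)::

    protein_id  family  subfamily  ec  tax_class  fragment

``subfamily`` may be empty; ``ec`` is a ";"-separated list of EC tokens,
each possibly joined by "&" (co-occurring functions of one protein) or "-"
(functions pooled from distinct source proteins); ``fragment`` is 0/1.

Domain-range TSV schema: ``protein_id  family  start  end`` with 0-based,
half-open coordinates.
"""

from __future__ import annotations

import gzip
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence, TextIO

import pandas as pd
from Bio import SeqIO
from scipy.cluster.hierarchy import to_tree

logger = logging.getLogger(__name__)

_EC_TOKEN = re.compile(r"^\d+\.\d+\.\d+\.(\d+|\*)$")


@dataclass(frozen=True)
class ProteinMeta:
    """One protein's annotation labels.

    ``ec_functions`` holds EC tokens; a single token may itself be an
    "&"-joined string (both functions carried by one protein) or a
    "-"-joined string (functions pooled from distinct source proteins).
    """

    family: str
    subfamily: int | None = None
    ec_functions: tuple[str, ...] = ()
    taxonomy_class: str | None = None
    is_fragment: bool = False

    def __post_init__(self) -> None:
        if self.subfamily is not None and self.subfamily < 1:
            raise ValueError(f"subfamily must be >= 1, got {self.subfamily}")
        for token in self.ec_functions:
            for part in re.split(r"[&-]", token):
                if not _EC_TOKEN.match(part):
                    raise ValueError(f"malformed EC token {token!r}")


@dataclass
class ProteinRecord:
    """A protein sequence with optional domain ranges and metadata evidence.

    ``metas`` is a list because a representative sequence inherits the
    metadata of every member of its high-similarity cluster; for an
    ordinary protein it has a single entry.
    """

    protein_id: str
    sequence: str
    domain_ranges: list[tuple[str, int, int]] | None = None
    metas: list[ProteinMeta] = field(default_factory=list)

    @property
    def meta(self) -> ProteinMeta | None:
        return self.metas[0] if self.metas else None

    @property
    def family(self) -> str | None:
        return self.metas[0].family if self.metas else None

    def domain_sequence(self, family: str) -> str:
        """Residues of this protein's domain(s) for ``family``.

        Falls back to the full-length sequence when no range for the family
        is recorded.
        """
        if not self.domain_ranges:
            return self.sequence
        parts = [
            self.sequence[start:end]
            for fam, start, end in self.domain_ranges
            if fam == family
        ]
        return "".join(parts) if parts else self.sequence


# ---------------------------------------------------------------------------
# FASTA


def _open_text(path: str | Path) -> TextIO:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read FASTA (optionally gzip-compressed) into (id, sequence) pairs.

    The id is the first whitespace-delimited token of the header; sequences
    are uppercased.  Duplicate ids raise an error naming the offenders.
    """
    pairs: list[tuple[str, str]] = []
    with _open_text(path) as handle:
        for rec in SeqIO.parse(handle, "fasta"):
            if not rec.id:
                raise ValueError(f"{path}: record with empty header")
            pairs.append((rec.id, str(rec.seq).upper()))
    seen: set[str] = set()
    dups = sorted({pid for pid, _ in pairs if pid in seen or seen.add(pid)})
    if dups:
        raise ValueError(f"{path}: duplicate protein ids {dups}")
    return pairs


def write_fasta(pairs: Iterable[tuple[str, str]], path: str | Path) -> None:
    with open(path, "w") as out:
        for pid, seq in pairs:
            out.write(f">{pid}\n")
            for i in range(0, len(seq), 60):
                out.write(seq[i : i + 60] + "\n")


# ---------------------------------------------------------------------------
# Metadata / domain TSV

META_COLUMNS = ["protein_id", "family", "subfamily", "ec", "tax_class", "fragment"]


def read_metadata(path: str | Path) -> dict[str, ProteinMeta]:
    """Read the per-protein metadata TSV into a mapping by protein id."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = set(META_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing metadata columns {sorted(missing)}")
    out: dict[str, ProteinMeta] = {}
    for row in df.itertuples(index=False):
        pid = row.protein_id
        if pid in out:
            raise ValueError(f"{path}: duplicate metadata row for {pid!r}")
        out[pid] = ProteinMeta(
            family=row.family,
            subfamily=int(row.subfamily) if row.subfamily else None,
            ec_functions=tuple(t for t in row.ec.split(";") if t),
            taxonomy_class=row.tax_class or None,
            is_fragment=bool(int(row.fragment)) if row.fragment else False,
        )
    return out


def write_metadata(metas: dict[str, ProteinMeta], path: str | Path) -> None:
    rows = [
        {
            "protein_id": pid,
            "family": m.family,
            "subfamily": "" if m.subfamily is None else m.subfamily,
            "ec": ";".join(m.ec_functions),
            "tax_class": m.taxonomy_class or "",
            "fragment": int(m.is_fragment),
        }
        for pid, m in metas.items()
    ]
    pd.DataFrame(rows, columns=META_COLUMNS).to_csv(path, sep="\t", index=False)


def read_domains(path: str | Path) -> dict[str, list[tuple[str, int, int]]]:
    """Read domain ranges (protein_id, family, start, end; 0-based half-open)."""
    df = pd.read_csv(path, sep="\t", dtype={"protein_id": str, "family": str})
    out: dict[str, list[tuple[str, int, int]]] = {}
    for row in df.itertuples(index=False):
        start, end = int(row.start), int(row.end)
        if not 0 <= start < end:
            raise ValueError(
                f"{path}: invalid range [{start}, {end}) for {row.protein_id}"
            )
        out.setdefault(row.protein_id, []).append((row.family, start, end))
    return out


def load_records(
    fasta_path: str | Path,
    meta_path: str | Path | None = None,
    domains_path: str | Path | None = None,
) -> list[ProteinRecord]:
    """Assemble :class:`ProteinRecord` objects from the on-disk artifacts."""
    metas = read_metadata(meta_path) if meta_path else {}
    domains = read_domains(domains_path) if domains_path else {}
    records = []
    for pid, seq in read_fasta(fasta_path):
        ranges = domains.get(pid)
        if ranges:
            for fam, start, end in ranges:
                if end > len(seq):
                    raise ValueError(
                        f"domain range [{start}, {end}) of {pid!r} exceeds "
                        f"sequence length {len(seq)}"
                    )
        m = metas.get(pid)
        records.append(
            ProteinRecord(
                protein_id=pid,
                sequence=seq,
                domain_ranges=ranges,
                metas=[m] if m else [],
            )
        )
    return records


# ---------------------------------------------------------------------------
# CD-HIT clusters


@dataclass
class RepresentativeMap:
    """Representative id -> member ids of its high-similarity cluster."""

    clusters: dict[str, set[str]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.clusters)

    def members(self) -> set[str]:
        out: set[str] = set()
        for mem in self.clusters.values():
            out.update(mem)
        return out


_CLSTR_ENTRY = re.compile(r">(?P<id>\S+?)\.\.\.")


def read_clstr(path: str | Path) -> RepresentativeMap:
    """Parse a CD-HIT ``.clstr`` file.

    Each ``>Cluster`` block lists member sequences; the ``*``-terminated
    line marks the representative.  A block without a representative is an
    error.
    """
    repmap = RepresentativeMap()
    block: list[tuple[str, bool]] = []
    block_index = -1

    def flush() -> None:
        if block_index < 0 and not block:
            return
        reps = [pid for pid, starred in block if starred]
        if len(reps) != 1:
            raise ValueError(
                f"{path}: cluster {block_index} has {len(reps)} representatives"
            )
        repmap.clusters[reps[0]] = {pid for pid, _ in block}

    with _open_text(path) as handle:
        for line in handle:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith(">Cluster"):
                if block:
                    flush()
                block = []
                block_index += 1
                continue
            m = _CLSTR_ENTRY.search(line)
            if not m:
                raise ValueError(f"{path}: unparseable cluster line {line!r}")
            block.append((m.group("id"), line.rstrip().endswith("*")))
        if block:
            flush()
    return repmap


def write_clstr(repmap: RepresentativeMap, path: str | Path) -> None:
    with open(path, "w") as out:
        for i, rep in enumerate(sorted(repmap.clusters)):
            out.write(f">Cluster {i}\n")
            members = sorted(repmap.clusters[rep])
            for j, pid in enumerate(members):
                mark = "*" if pid == rep else "at 90.00%"
                out.write(f"{j}\t100aa, >{pid}... {mark}\n")


def select_representatives(
    records: Sequence[ProteinRecord],
    repmap: RepresentativeMap | None = None,
) -> list[ProteinRecord]:
    """Reduce a record collection to one representative per cluster.

    Fragment-flagged records are dropped first.  With a representative map,
    each representative inherits the metadata of all surviving members;
    duplicate (protein, metadata) pairs are collapsed so an identical
    metadata string of an identical protein never counts twice.  Without a
    map, records pass through (minus fragments).
    """
    by_id = {r.protein_id: r for r in records}
    kept = []
    for r in records:
        if any(m.is_fragment for m in r.metas):
            logger.info("dropping fragment-flagged record %s", r.protein_id)
            continue
        kept.append(r)
    if repmap is None:
        return kept
    unknown = repmap.members() - set(by_id)
    if unknown:
        raise ValueError(f"cluster file names unknown protein ids {sorted(unknown)}")
    kept_ids = {r.protein_id for r in kept}
    out: list[ProteinRecord] = []
    clustered: set[str] = set()
    for rep in sorted(repmap.clusters):
        member_ids = sorted(repmap.clusters[rep] & kept_ids)
        clustered.update(repmap.clusters[rep])
        if not member_ids:
            logger.info("cluster of %s dropped: all members are fragments", rep)
            continue
        rep_id = rep if rep in member_ids else member_ids[0]
        seen_meta: set[tuple[str, ProteinMeta]] = set()
        metas: list[ProteinMeta] = []
        for pid in member_ids:
            for m in by_id[pid].metas:
                key = (pid, m)
                if key not in seen_meta:
                    seen_meta.add(key)
                    metas.append(m)
        base = by_id[rep_id]
        out.append(
            ProteinRecord(
                protein_id=rep_id,
                sequence=base.sequence,
                domain_ranges=base.domain_ranges,
                metas=metas,
            )
        )
    # records not mentioned by the cluster file pass through untouched
    out.extend(r for r in kept if r.protein_id not in clustered)
    out.sort(key=lambda r: r.protein_id)
    return out


# ---------------------------------------------------------------------------
# Newick export


def _escape_label(label: str) -> str:
    if re.search(r"[\s()\[\]',;:]", label):
        return "'" + label.replace("'", "''") + "'"
    return label


def write_newick(linkage_matrix, labels: Sequence[str]) -> str:
    """Convert a scipy linkage matrix into a Newick string.

    Branch lengths are differences of merge heights, so the root-to-leaf
    path length of each leaf equals the total tree height.  Labels with
    Newick metacharacters are quoted.
    """
    if len(labels) < 2:
        raise ValueError("need at least 2 leaves to build a tree")
    root = to_tree(linkage_matrix)

    def recurse(node, parent_height: float) -> str:
        length = float(parent_height) - float(node.dist)
        if node.is_leaf():
            return f"{_escape_label(labels[node.id])}:{length!r}"
        left = recurse(node.left, node.dist)
        right = recurse(node.right, node.dist)
        return f"({left},{right}):{length!r}"

    left = recurse(root.left, root.dist)
    right = recurse(root.right, root.dist)
    return f"({left},{right});"


# ---------------------------------------------------------------------------
# Annotation TSV

ANNOTATION_COLUMNS = [
    "query_id",
    "family",
    "group_label",
    "ranges",
    "score",
    "frac_of_max",
    "subfamily",
    "ec",
    "mode",
]


def write_annotations(rows: Sequence[dict], path: str | Path) -> None:
    """Write annotation rows (dicts keyed by ANNOTATION_COLUMNS) as TSV."""
    df = pd.DataFrame(list(rows), columns=ANNOTATION_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


def read_annotations(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = set(ANNOTATION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing annotation columns {sorted(missing)}")
    return df
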