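"""Synthetic protein families with known group structure.

The generator emulates a single enzyme family composed of several
ancestral groups: each group has a random ancestor (re-drawn until all
ancestor pairs fall below a maximum identity), and members are
point-mutated copies of their ancestor under a star phylogeny.
Substitutions always change the residue, so the expected member-ancestor
identity is exactly ``1 - within_mutation_rate``.

Ancestors are not fully independent: a short *family core* — the leading
``family_core_fraction`` of the ancestor length — is shared by every
ancestor, mimicking the family-wide conserved catalytic motifs that make
distant members of a real enzyme family recognizable as the family even
when they fall in no existing group.  The remaining positions are i.i.d.
per ancestor.  Per-group subfamily and EC labels, optional fragment
flags, and 70%-identity clusters (the atomic units for cross-validation
folds) are emitted alongside, so clustering, library building,
prediction, and evaluation are all testable offline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .family_io import ProteinMeta, ProteinRecord, RepresentativeMap

AMINO_ACIDS = np.array(list("ACDEFGHIKLMNPQRSTVWY"))

CLUSTER_IDENTITY = 0.70
_MAX_REDRAWS = 200


@dataclass(frozen=True)
class SyntheticFamilySpec:
    """Study conditions for one generated family."""

    family: str = "GH99"
    n_groups: int = 5
    members_per_group: int = 12
    ancestor_length: int = 300
    within_mutation_rate: float = 0.03
    between_identity: float = 0.5
    family_core_fraction: float = 0.10
    fragment_fraction: float = 0.0
    seed: int = 0
    subfamily_map: dict[int, int] = field(default_factory=dict)
    ec_map: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for rate in (self.within_mutation_rate, self.between_identity,
                     self.family_core_fraction, self.fragment_fraction):
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"rates must lie in [0, 1], got {rate}")
        if self.ancestor_length < 24:
            raise ValueError("ancestors must span at least three peptide windows")
        if self.family_core_fraction > self.between_identity:
            raise ValueError(
                "the shared family core cannot exceed the between-group "
                "identity cap"
            )

    def subfamily_of(self, group: int) -> int:
        return self.subfamily_map.get(group, group)

    def ec_of(self, group: int) -> str:
        return self.ec_map.get(group, f"3.2.1.{group}")


def _identity(a: str, b: str) -> float:
    """Fraction of matching positions over the longer length."""
    m = sum(x == y for x, y in zip(a, b))
    return m / max(len(a), len(b))


def _draw_ancestors(spec: SyntheticFamilySpec, rng: np.random.Generator) -> list[str]:
    core_len = int(round(spec.family_core_fraction * spec.ancestor_length))
    core = "".join(rng.choice(AMINO_ACIDS, size=core_len))
    tail_len = spec.ancestor_length - core_len
    ancestors: list[str] = []
    for _ in range(spec.n_groups):
        for _attempt in range(_MAX_REDRAWS):
            candidate = core + "".join(rng.choice(AMINO_ACIDS, size=tail_len))
            if all(
                _identity(candidate, other) <= spec.between_identity
                for other in ancestors
            ):
                ancestors.append(candidate)
                break
        else:
            raise RuntimeError(
                f"could not draw ancestors below identity "
                f"{spec.between_identity} in {_MAX_REDRAWS} attempts"
            )
    return ancestors


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Substitute each position with probability ``rate``, never silently."""
    chars = np.array(list(seq))
    hit = rng.random(len(chars)) < rate
    for i in np.flatnonzero(hit):
        choices = AMINO_ACIDS[AMINO_ACIDS != chars[i]]
        chars[i] = rng.choice(choices)
    return "".join(chars)


def similarity_clusters(
    sequences: dict[str, str], threshold: float = CLUSTER_IDENTITY
) -> RepresentativeMap:
    """Single-linkage clusters of sequences at a pairwise-identity threshold.

    Connected components of the "identity >= threshold" graph; the
    representative of each component is its lexicographically smallest id.
    These clusters are the atomic units for cluster-aware fold splitting.
    """
    ids = sorted(sequences)
    parent = {pid: pid for pid in ids}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            if _identity(sequences[a], sequences[b]) >= threshold:
                ra, rb = find(a), find(b)
                if ra != rb:
                    parent[max(ra, rb)] = min(ra, rb)
    clusters: dict[str, set[str]] = {}
    for pid in ids:
        clusters.setdefault(find(pid), set()).add(pid)
    return RepresentativeMap(clusters=clusters)


def generate_family(
    spec: SyntheticFamilySpec,
) -> tuple[list[ProteinRecord], dict[str, int], RepresentativeMap]:
    """Generate one family with known group structure.

    Returns the records (with metadata attached), the generative truth as
    protein id -> group number (1-based), and the 70%-identity clusters.
    Fully reproducible from ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    ancestors = _draw_ancestors(spec, rng)
    records: list[ProteinRecord] = []
    truth: dict[str, int] = {}
    sequences: dict[str, str] = {}
    n_total = spec.n_groups * spec.members_per_group
    n_fragments = int(round(spec.fragment_fraction * n_total))
    fragment_ids: set[int] = (
        set(rng.choice(n_total, size=n_fragments, replace=False))
        if n_fragments
        else set()
    )
    counter = 0
    for gi, ancestor in enumerate(ancestors, start=1):
        for mi in range(1, spec.members_per_group + 1):
            pid = f"{spec.family}_g{gi:02d}_m{mi:03d}"
            seq = _mutate(ancestor, spec.within_mutation_rate, rng)
            meta = ProteinMeta(
                family=spec.family,
                subfamily=spec.subfamily_of(gi),
                ec_functions=(spec.ec_of(gi),),
                taxonomy_class="Bacteria" if gi % 2 else "Eukaryota",
                is_fragment=counter in fragment_ids,
            )
            records.append(
                ProteinRecord(protein_id=pid, sequence=seq, metas=[meta])
            )
            truth[pid] = gi
            sequences[pid] = seq
            counter += 1
    clusters = similarity_clusters(sequences)
    return records, truth, clusters


def generate_multidomain(
    spec_a: SyntheticFamilySpec,
    spec_b: SyntheticFamilySpec,
    linker_length: int = 20,
) -> tuple[list[ProteinRecord], dict[str, list[tuple[str, int, int]]]]:
    """Concatenate members of two families through a poly-G linker.

    Poly-G linkers are used because all-glycine windows are banned from
    peptide libraries, so the linker can never score.  Returns the fused
    records and the truth ranges (family, start, end) per protein.
    """
    if spec_a.family == spec_b.family:
        raise ValueError("the two specs must describe different families")
    records_a, _, _ = generate_family(spec_a)
    records_b, _, _ = generate_family(spec_b)
    linker = "G" * linker_length
    fused: list[ProteinRecord] = []
    truth_ranges: dict[str, list[tuple[str, int, int]]] = {}
    for i, (ra, rb) in enumerate(zip(records_a, records_b)):
        pid = f"MD_{i:03d}"
        seq = ra.sequence + linker + rb.sequence
        offset = len(ra.sequence) + linker_length
        ranges = [
            (spec_a.family, 0, len(ra.sequence)),
            (spec_b.family, offset, offset + len(rb.sequence)),
        ]
        fused.append(
            ProteinRecord(
                protein_id=pid,
                sequence=seq,
                domain_ranges=ranges,
                metas=ra.metas + rb.metas,
            )
        )
        truth_ranges[pid] = ranges
    return fused, truth_ranges
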