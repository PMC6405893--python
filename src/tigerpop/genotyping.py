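"""Consensus genotyping from replicate amplifications.

Fecal-DNA microsatellite genotypes are error-prone (allelic dropout,
false alleles, failed amplifications), so every sample is amplified
several times and a per-locus *consensus* call is accepted only when it
is replicated: a homozygote must be seen in at least three replicates, a
heterozygote (the same unordered allele pair) in at least two.  Samples
whose confirmed multilocus genotypes are near-identical (at most one
mismatching allele) are merged into individuals, and sex is assigned
from X/Y marker amplification outcomes (ZFX / DBY7).

Also hosts a reader/writer for the Genepop text format used to exchange
population genotype tables.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

Call = tuple[int, int]  # unordered allele-size pair, stored sorted ascending

CONFIRMED = "confirmed"
UNRESOLVED = "unresolved"
MISSING = "missing"


def _norm_call(call: Sequence[int] | None) -> Call | None:
    if call is None:
        return None
    a, b = int(call[0]), int(call[1])
    return (a, b) if a <= b else (b, a)


@dataclass
class ReplicateGenotype:
    """Allele calls from one PCR replicate of one sample.

    ``calls`` maps locus name to a sorted allele-size pair, or ``None``
    for a failed/missing locus.
    """

    sample_id: str
    replicate_index: int
    calls: dict[str, Call | None]

    def __post_init__(self) -> None:
        self.calls = {loc: _norm_call(c) for loc, c in self.calls.items()}


@dataclass
class ConsensusGenotype:
    """Replication-confirmed multilocus genotype for one sample."""

    sample_id: str
    calls: dict[str, Call | None]
    locus_status: dict[str, str]
    n_replicates_used: int

    @property
    def typed_allele_count(self) -> int:
        """Two alleles per confirmed locus."""
        return 2 * sum(1 for s in self.locus_status.values() if s == CONFIRMED)

    def confirmed_loci(self) -> list[str]:
        return [l for l, s in self.locus_status.items() if s == CONFIRMED]


@dataclass
class Individual:
    """A genetically identified individual (one or more merged samples)."""

    individual_id: str
    member_sample_ids: list[str]
    genotype: dict[str, Call | None]
    population_label: str | None = None
    sex: str = "unknown"
    coordinates: list[tuple[float, float]] = field(default_factory=list)
    merge_conflict: bool = False

    @property
    def n_samples(self) -> int:
        return len(self.member_sample_ids)

    def typed_loci(self) -> list[str]:
        return [l for l, c in self.genotype.items() if c is not None]


# ---------------------------------------------------------------------------
# consensus calling


def call_consensus(
    replicates: Iterable[ReplicateGenotype],
    min_hom: int = 3,
    min_het: int = 2,
    loci: Sequence[str] | None = None,
) -> ConsensusGenotype:
    """Combine replicate allele calls for one sample into a consensus.

    A homozygous call is confirmed when the same homozygote appears in at
    least ``min_hom`` replicates; a heterozygous call when the identical
    unordered pair appears in at least ``min_het`` replicates.  When no
    genotype meets its threshold, or two conflicting genotypes both do,
    the locus is left ``unresolved`` (treated as missing downstream).
    Additional replicates may be supplied later and the consensus
    re-called.
    """
    reps = list(replicates)
    if not reps:
        raise ValueError("call_consensus requires at least one replicate")
    sample_ids = {r.sample_id for r in reps}
    if len(sample_ids) != 1:
        raise ValueError(
            f"replicates from different samples: {sorted(sample_ids)}"
        )
    indices = [r.replicate_index for r in reps]
    if len(set(indices)) != len(indices):
        raise ValueError(f"duplicate replicate_index for sample {reps[0].sample_id}")

    if loci is None:
        seen: dict[str, None] = {}
        for r in reps:
            for loc in r.calls:
                seen.setdefault(loc, None)
        loci = list(seen)

    calls: dict[str, Call | None] = {}
    status: dict[str, str] = {}
    for loc in loci:
        observed = [r.calls.get(loc) for r in reps]
        present = [c for c in observed if c is not None]
        if not present:
            calls[loc], status[loc] = None, MISSING
            continue
        counts = Counter(present)
        confirmed = [
            g
            for g, k in counts.items()
            if k >= (min_hom if g[0] == g[1] else min_het)
        ]
        if len(confirmed) == 1:
            calls[loc], status[loc] = confirmed[0], CONFIRMED
        else:
            calls[loc], status[loc] = None, UNRESOLVED
    return ConsensusGenotype(
        sample_id=reps[0].sample_id,
        calls=calls,
        locus_status=status,
        n_replicates_used=len(reps),
    )


def filter_usable(consensus: ConsensusGenotype, min_alleles: int = 14) -> bool:
    """Usability gate: the multilocus genotype must carry at least
    ``min_alleles`` confirmed alleles (14 = 7 of 8 loci)."""
    return consensus.typed_allele_count >= min_alleles


# ---------------------------------------------------------------------------
# individual matching


def genotype_mismatches(
    a: Mapping[str, Call | None], b: Mapping[str, Call | None]
) -> int:
    """Number of mismatching allele positions over loci typed in both.

    Per locus the two unordered pairs contribute ``2 - |multiset
    intersection|`` mismatches; loci missing in either sample contribute
    none.
    """
    total = 0
    for loc, ca in a.items():
        cb = b.get(loc)
        if ca is None or cb is None:
            continue
        shared = sum((Counter(ca) & Counter(cb)).values())
        total += 2 - shared
    return total


def match_individuals(
    genotypes: Sequence[ConsensusGenotype],
    max_mismatch: int = 1,
    metadata: Mapping[str, Mapping] | None = None,
) -> list[Individual]:
    """Merge samples into individuals by single-linkage on genotype
    mismatch counts.

    Samples differing at ``<= max_mismatch`` allele positions are linked;
    linkage is transitive, and a cluster containing a pair that itself
    exceeds the threshold (a transitivity conflict) is still merged but
    flagged.  The merged call at each locus is the one confirmed in the
    majority of member samples (ties broken by frequency then by the
    numerically smallest pair).  ``metadata`` may map sample_id to a dict
    with ``population``, ``lon``, ``lat`` keys.
    """
    if not genotypes:
        return []
    # canonical order makes the merge independent of input order
    gts = sorted(genotypes, key=lambda g: g.sample_id)
    n = len(gts)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[max(ri, rj)] = min(ri, rj)

    mism = {}
    for i in range(n):
        for j in range(i + 1, n):
            mism[i, j] = genotype_mismatches(gts[i].calls, gts[j].calls)
            if mism[i, j] <= max_mismatch:
                union(i, j)

    clusters: dict[int, list[int]] = {}
    for i in range(n):
        clusters.setdefault(find(i), []).append(i)

    individuals: list[Individual] = []
    for k, root in enumerate(sorted(clusters)):
        members = clusters[root]
        conflict = any(
            mism[min(i, j), max(i, j)] > max_mismatch
            for ai, i in enumerate(members)
            for j in members[ai + 1 :]
        )
        loci: dict[str, None] = {}
        for i in members:
            for loc in gts[i].calls:
                loci.setdefault(loc, None)
        merged: dict[str, Call | None] = {}
        for loc in loci:
            votes = Counter(
                gts[i].calls[loc]
                for i in members
                if gts[i].calls.get(loc) is not None
            )
            if votes:
                merged[loc] = min(
                    votes, key=lambda g: (-votes[g], g)
                )
            else:
                merged[loc] = None
        sample_ids = [gts[i].sample_id for i in members]
        pop = None
        coords: list[tuple[float, float]] = []
        if metadata:
            pops = [
                metadata[s]["population"]
                for s in sample_ids
                if s in metadata and "population" in metadata[s]
            ]
            if pops:
                pop = Counter(pops).most_common(1)[0][0]
            for s in sample_ids:
                m = metadata.get(s, {})
                if "lon" in m and "lat" in m:
                    coords.append((float(m["lon"]), float(m["lat"])))
        individuals.append(
            Individual(
                individual_id=f"IND{k + 1:03d}",
                member_sample_ids=sample_ids,
                genotype=merged,
                population_label=pop,
                coordinates=coords,
                merge_conflict=conflict,
            )
        )
    return individuals


# ---------------------------------------------------------------------------
# sex assignment


def assign_sex(
    marker_results: Sequence[tuple[bool, bool]],
    positive_control_ok: bool = True,
    negative_control_clean: bool = True,
    min_dby7_negative: int = 3,
) -> str:
    """Sex call from replicate (ZFX amplified, DBY7 amplified) outcomes.

    Male: the Y-linked DBY7 fragment amplifies in any replicate with a
    clean negative control.  Female: the X-linked ZFX fragment amplifies
    while DBY7 fails in at least ``min_dby7_negative`` replicates, with a
    successful positive control (so the DBY7 failures are not PCR
    failures).  A contaminated negative control voids all calls.
    """
    if not negative_control_clean:
        return "unknown"
    zfx_pos = sum(1 for z, _ in marker_results if z)
    dby7_pos = sum(1 for _, y in marker_results if y)
    dby7_neg = sum(1 for _, y in marker_results if not y)
    if dby7_pos >= 1:
        return "male"
    if zfx_pos >= 1 and dby7_neg >= min_dby7_negative and positive_control_ok:
        return "female"
    return "unknown"


# ---------------------------------------------------------------------------
# Genepop text format


@dataclass
class GenepopTable:
    """In-memory image of a Genepop file: a title, ordered locus names,
    and per-population lists of ``(sample_id, calls)``."""

    title: str
    loci: list[str]
    populations: list[list[tuple[str, dict[str, Call | None]]]]


def write_genepop(table: GenepopTable, path, digits: int = 3) -> None:
    """Write a Genepop v4-style text file (``digits`` = 2 or 3 per allele;
    all-zero codes mean missing)."""
    if digits not in (2, 3):
        raise ValueError("allele coding must use 2 or 3 digits")
    lines = [table.title]
    lines.extend(table.loci)
    for pop in table.populations:
        lines.append("Pop")
        for sample_id, calls in pop:
            codes = []
            for loc in table.loci:
                c = calls.get(loc)
                if c is None:
                    codes.append("0" * (2 * digits))
                else:
                    codes.append(f"{c[0]:0{digits}d}{c[1]:0{digits}d}")
            lines.append(f"{sample_id} ,  " + " ".join(codes))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def parse_genepop(path) -> GenepopTable:
    """Read a Genepop text file (2- or 3-digit allele coding)."""
    with open(path) as fh:
        raw = fh.read().splitlines()
    if not raw:
        raise ValueError(f"{path}: empty Genepop file")
    title = raw[0]
    loci: list[str] = []
    i = 1
    while i < len(raw) and raw[i].strip().lower() != "pop":
        line = raw[i].strip()
        if line:
            if "," in line:
                loci.extend(x.strip() for x in line.split(",") if x.strip())
            else:
                loci.append(line)
        i += 1
    if i == len(raw):
        raise ValueError(f"{path}: no 'Pop' line found")
    populations: list[list[tuple[str, dict[str, Call | None]]]] = []
    current: list[tuple[str, dict[str, Call | None]]] | None = None
    for lineno in range(i, len(raw)):
        line = raw[lineno].strip()
        if not line:
            continue
        if line.lower() == "pop":
            current = []
            populations.append(current)
            continue
        if "," not in line:
            raise ValueError(f"{path}:{lineno + 1}: expected 'id , genotypes'")
        sid, rest = line.split(",", 1)
        tokens = rest.split()
        if len(tokens) != len(loci):
            raise ValueError(
                f"{path}:{lineno + 1}: {len(tokens)} genotypes for "
                f"{len(loci)} loci"
            )
        calls: dict[str, Call | None] = {}
        for loc, tok in zip(loci, tokens):
            if len(tok) not in (4, 6) or not tok.isdigit():
                raise ValueError(
                    f"{path}:{lineno + 1}: bad genotype code {tok!r} at {loc}"
                )
            d = len(tok) // 2
            a, b = int(tok[:d]), int(tok[d:])
            calls[loc] = None if a == 0 or b == 0 else _norm_call((a, b))
        current.append((sid.strip(), calls))
    return GenepopTable(title=title, loci=loci, populations=populations)
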