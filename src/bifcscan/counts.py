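"""Codon-level variant counting from amplicon reads.

Reads are matched by exact ungapped comparison against the reference CDS
fragment they came from (amplicon coordinates are fixed, so no aligner is
involved). A read counts toward the wild type when it matches the fragment
reference exactly, toward a single-substitution variant when exactly one
codon differs and translates to a non-reference amino acid, and is
otherwise discarded with a reason code.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from collections import Counter

from Bio import SeqIO
from Bio.Seq import Seq

from .core import (
    AA_ALPHABET,
    Fragment,
    ReferenceProtein,
    ValidationError,
    STOP,
    VariantKey,
    check_fragments,
    whole_cds_fragment,
)
from .simulate import SortResult

_HEADER_RE = re.compile(r"^(?P<cond>[^:]+):(?P<frag>[^:]+):(?P<start>\d+)-(?P<end>\d+):\d+$")


@dataclass
class CountTable:
    """Per-condition single-mutant counts against a reference.

    ``wt_depth`` maps each covered residue position to the number of fully
    wild-type reads from fragments covering it; it is the effective WT
    depth used for per-position frequency computation and differs from
    ``wt_count`` only after merging overlapping fragments.
    """

    condition: str
    reference: ReferenceProtein
    counts: dict[VariantKey, int]
    wt_count: int
    discarded: dict[str, int]
    total_reads: int
    positions: frozenset[int]
    wt_depth: dict[int, int]
    replicate: str = ""

    def validate(self) -> "CountTable":
        if any(c < 0 for c in self.counts.values()) or self.wt_count < 0:
            raise ValidationError("counts must be nonnegative")
        for v in self.counts:
            self.reference.validate_variant(v)
        total = self.wt_count + sum(self.counts.values()) + sum(self.discarded.values())
        if total != self.total_reads:
            raise ValidationError(
                f"count bookkeeping broken: wt {self.wt_count} + variants + discarded = {total}"
                f" != total_reads {self.total_reads}"
            )
        return self

    def position_depth(self, position: int) -> int:
        """WT depth plus single-mutant counts at one residue position."""
        at_pos = sum(c for v, c in self.counts.items() if v.position == position)
        return self.wt_depth.get(position, 0) + at_pos


def counts_from_simulation(sim: SortResult, condition: str, replicate: str = "") -> CountTable:
    """Turn a simulated condition's read counts into a CountTable
    (equivalent to error-free whole-CDS reads)."""
    reads = sim.conditions[condition].reads
    wt = reads.get(None, 0)
    counts = {v: c for v, c in reads.items() if v is not None and c > 0}
    positions = frozenset(range(1, len(sim.reference) + 1))
    return CountTable(
        condition=condition,
        reference=sim.reference,
        counts=counts,
        wt_count=wt,
        discarded={},
        total_reads=wt + sum(counts.values()),
        positions=positions,
        wt_depth={p: wt for p in positions},
        replicate=replicate,
    ).validate()


def _identify_fragment(record_id: str, seq_len: int, fragments: list[Fragment]) -> Fragment:
    m = _HEADER_RE.match(record_id)
    if m:
        for fr in fragments:
            if fr.name == m.group("frag") and fr.start == int(m.group("start")) and fr.end == int(m.group("end")):
                return fr
    by_len = [fr for fr in fragments if len(fr) == seq_len]
    if len(by_len) == 1:
        return by_len[0]
    raise ValidationError(f"cannot identify the fragment of read {record_id!r} (length {seq_len})")


def call_codon_variants(
    reads,
    ref: ReferenceProtein,
    fragments: list[Fragment] | None = None,
    max_mismatch_codons: int = 1,
    alphabet: str = AA_ALPHABET,
    min_qual: int | None = None,
    condition: str = "",
    replicate: str = "",
) -> dict[Fragment, CountTable]:
    """Count codon-level single mutants per fragment from a FASTQ stream.

    ``reads`` is a path or handle of FASTQ records whose fragment is
    identifiable from the simulator-style header (condition:frag:start-end:n)
    or, failing that, uniquely by read length. Reads whose length does not
    match their fragment are discarded as indel_or_unaligned; reads with
    more than ``max_mismatch_codons`` mutated codons as multi_mutant; a
    single mutated codon must be unambiguous, non-synonymous, and translate
    to a letter of ``alphabet`` (premature stops are discarded unless '*'
    is in the alphabet). With ``min_qual``, mismatch bases below the
    threshold discard the read as low_quality.

    Returns one CountTable per fragment; merge with
    :func:`merge_fragment_counts`.
    """
    if fragments is None:
        fragments = [whole_cds_fragment(ref)]
    check_fragments(ref, fragments)
    per_frag = {
        fr: {"counts": Counter(), "wt": 0, "disc": Counter(), "total": 0} for fr in fragments
    }
    frag_ref = {fr: ref.cds[fr.start - 1 : fr.end] for fr in fragments}
    n_records = 0
    for rec in SeqIO.parse(reads, "fastq"):
        n_records += 1
        seq = str(rec.seq).upper()
        fr = _identify_fragment(rec.id, len(seq), fragments)
        acc = per_frag[fr]
        acc["total"] += 1
        template = frag_ref[fr]
        if len(seq) != len(template):
            acc["disc"]["indel_or_unaligned"] += 1
            continue
        mismatch_codons = [
            i for i in range(len(template) // 3) if seq[3 * i : 3 * i + 3] != template[3 * i : 3 * i + 3]
        ]
        if not mismatch_codons:
            acc["wt"] += 1
            continue
        if len(mismatch_codons) > max_mismatch_codons or len(mismatch_codons) > 1:
            acc["disc"]["multi_mutant"] += 1
            continue
        i = mismatch_codons[0]
        codon = seq[3 * i : 3 * i + 3]
        if any(b not in "ACGT" for b in codon):
            acc["disc"]["ambiguous_base"] += 1
            continue
        if min_qual is not None:
            quals = rec.letter_annotations.get("phred_quality")
            if quals and min(quals[3 * i : 3 * i + 3]) < min_qual:
                acc["disc"]["low_quality"] += 1
                continue
        aa = str(Seq(codon).translate())
        position = (fr.start - 1) // 3 + i + 1
        wt_aa = ref.wt_aa(position)
        if aa == wt_aa:
            acc["disc"]["synonymous"] += 1
            continue
        if aa == STOP and STOP not in alphabet:
            acc["disc"]["premature_stop"] += 1
            continue
        if aa not in alphabet:
            acc["disc"]["not_in_alphabet"] += 1
            continue
        acc["counts"][VariantKey(position, wt_aa, aa)] += 1
    if n_records == 0:
        raise ValidationError("empty read stream")
    tables = {}
    for fr, acc in per_frag.items():
        positions = frozenset(fr.residue_positions)
        tables[fr] = CountTable(
            condition=condition,
            reference=ref,
            counts=dict(acc["counts"]),
            wt_count=acc["wt"],
            discarded=dict(acc["disc"]),
            total_reads=acc["total"],
            positions=positions,
            wt_depth={p: acc["wt"] for p in positions},
            replicate=replicate,
        ).validate()
    return tables


def merge_fragment_counts(tables: list[CountTable]) -> CountTable:
    """Merge per-fragment tables of one condition into a single table.

    Variant counts sum across fragments; the per-position effective WT
    depth is the sum of wild-type read counts over fragments covering that
    position, so overlapping fragments contribute additively to depth.
    """
    if not tables:
        raise ValidationError("no tables to merge")
    first = tables[0]
    for t in tables[1:]:
        if t.reference.name != first.reference.name or t.reference.cds != first.reference.cds:
            raise ValidationError("cannot merge tables with conflicting references")
        if t.condition != first.condition or t.replicate != first.replicate:
            raise ValidationError("cannot merge tables from different conditions")
    counts: Counter = Counter()
    discarded: Counter = Counter()
    wt_depth: Counter = Counter()
    wt_count = 0
    total = 0
    positions: set[int] = set()
    for t in tables:
        t.validate()
        counts.update(t.counts)
        discarded.update(t.discarded)
        wt_count += t.wt_count
        total += t.total_reads
        positions.update(t.positions)
        for p, d in t.wt_depth.items():
            wt_depth[p] += d
    return CountTable(
        condition=first.condition,
        reference=first.reference,
        counts=dict(counts),
        wt_count=wt_count,
        discarded=dict(discarded),
        total_reads=total,
        positions=frozenset(positions),
        wt_depth=dict(wt_depth),
        replicate=first.replicate,
    ).validate()
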