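"""Plain-text table I/O.

Count tables travel as CSV with columns condition, position, wt_aa,
mut_aa, count. Wild-type bookkeeping rides along in the same schema:
per-position effective WT depth rows carry mut_aa "WT", the single total
WT read count row has position 0 / mut_aa "WT_TOTAL", and discard tallies
have mut_aa "DISCARDED:<reason>".
"""

from __future__ import annotations

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

from .core import ReferenceProtein, ValidationError, VariantKey
from .counts import CountTable


def read_reference_fasta(path, name: str | None = None) -> ReferenceProtein:
    """Read a coding sequence FASTA (one record) into a ReferenceProtein."""
    records = list(SeqIO.parse(path, "fasta"))
    if len(records) != 1:
        raise ValidationError(f"expected one CDS record in {path}, found {len(records)}")
    rec = records[0]
    cds = str(rec.seq).upper()
    # tolerate a trailing stop codon in the supplied ORF
    if len(cds) % 3 == 0 and cds[-3:] in ("TAA", "TAG", "TGA"):
        cds = cds[:-3]
    return ReferenceProtein(name or rec.id, str(Seq(cds).translate()), cds)


def write_count_table(table: CountTable, path) -> None:
    rows = [
        {"condition": table.condition, "position": v.position, "wt_aa": v.wt_aa, "mut_aa": v.mut_aa, "count": c}
        for v, c in sorted(table.counts.items())
    ]
    for pos in sorted(table.positions):
        rows.append(
            {
                "condition": table.condition,
                "position": pos,
                "wt_aa": table.reference.wt_aa(pos),
                "mut_aa": "WT",
                "count": table.wt_depth.get(pos, 0),
            }
        )
    rows.append({"condition": table.condition, "position": 0, "wt_aa": "-", "mut_aa": "WT_TOTAL", "count": table.wt_count})
    for reason, c in sorted(table.discarded.items()):
        rows.append({"condition": table.condition, "position": 0, "wt_aa": "-", "mut_aa": f"DISCARDED:{reason}", "count": c})
    pd.DataFrame(rows).to_csv(path, index=False)


def read_count_table(path, ref: ReferenceProtein, replicate: str = "") -> CountTable:
    df = pd.read_csv(path)
    conditions = df["condition"].unique()
    if len(conditions) != 1:
        raise ValidationError(f"count table must hold one condition, found {list(conditions)}")
    counts: dict[VariantKey, int] = {}
    wt_depth: dict[int, int] = {}
    wt_count = 0
    discarded: dict[str, int] = {}
    for r in df.itertuples():
        if r.mut_aa == "WT":
            wt_depth[int(r.position)] = int(r.count)
        elif r.mut_aa == "WT_TOTAL":
            wt_count = int(r.count)
        elif str(r.mut_aa).startswith("DISCARDED:"):
            discarded[str(r.mut_aa).split(":", 1)[1]] = int(r.count)
        else:
            counts[ref.validate_variant(VariantKey(int(r.position), r.wt_aa, r.mut_aa))] = int(r.count)
    return CountTable(
        condition=str(conditions[0]),
        reference=ref,
        counts=counts,
        wt_count=wt_count,
        discarded=discarded,
        total_reads=wt_count + sum(counts.values()) + sum(discarded.values()),
        positions=frozenset(wt_depth),
        wt_depth=wt_depth,
        replicate=replicate,
    ).validate()


def write_enrichment_table(table: pd.DataFrame, path) -> None:
    meta = f"# selection={table.attrs.get('selection', '')} replicate={table.attrs.get('replicate', '')} pseudocount={table.attrs.get('pseudocount', '')}\n"
    with open(path, "w") as fh:
        fh.write(meta)
        table.to_csv(fh, sep="\t", index=False)


def read_enrichment_table(path) -> pd.DataFrame:
    with open(path) as fh:
        header = fh.readline()
        df = pd.read_csv(fh, sep="\t")
    if header.startswith("#"):
        for tok in header[1:].split():
            if "=" in tok:
                k, v = tok.split("=", 1)
                df.attrs[k] = v
    return df
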