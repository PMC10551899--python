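"""Project per-residue conservation scores onto a structure.

Scores are written into the per-atom temperature-factor (B-factor) column
of a copy of the structure, clamped to the display range [-3, +3], so any
molecular viewer can color a surface by mutational tolerance; a plain-text
attribute file retains the unclamped values. Residue numbering is related
to profile positions by a single integer offset per chain
(profile position + offset = structure residue number).
"""

from __future__ import annotations

from dataclasses import dataclass

import gemmi
import numpy as np
import pandas as pd

from .core import ValidationError, UNMAPPED_BFACTOR


@dataclass
class StructureAnnotation:
    """Result of mapping a conservation profile onto one chain."""

    structure_file: str
    chain: str
    numbering_offset: int
    mapped: dict[int, float]  # profile position -> unclamped score
    unmapped: list[int]  # profile positions with no structure residue
    pdb_out: str | None = None
    attr_out: str | None = None


def _load_chain(structure_file: str, chain: str) -> tuple[gemmi.Structure, gemmi.Chain]:
    st = gemmi.read_structure(str(structure_file))
    st.setup_entities()
    model = st[0]
    ch = model.find_chain(chain)
    if ch is None:
        raise ValidationError(f"chain {chain!r} not found in {structure_file}")
    return st, ch


def clamp(score: float, lo: float = -3.0, hi: float = 3.0) -> float:
    return min(hi, max(lo, score))


def map_scores_to_structure(
    profile: pd.DataFrame,
    structure_file: str,
    chain: str,
    numbering_offset: int = 0,
    clamp_range: tuple[float, float] = (-3.0, 3.0),
    pdb_out: str | None = None,
    attr_out: str | None = None,
) -> StructureAnnotation:
    """Write conservation scores into a structure's B-factor column.

    Every atom of a matched residue of the target chain carries the
    clamped score; every other residue in the structure gets the sentinel
    99.0 so unscored regions are unambiguous in a viewer. The attribute
    file (one "resnum<TAB>score" line, full precision, unclamped) is the
    input for external rendering. Profile positions with no residue in
    the chain are returned as unmapped; if nothing maps, that is a hard
    error.
    """
    if profile.empty:
        raise ValidationError("empty conservation profile")
    st, ch = _load_chain(structure_file, chain)
    scores = {int(p): float(s) for p, s in profile["score"].items() if np.isfinite(s)}
    lo, hi = clamp_range
    for model in st:
        for c in model:
            for res in c:
                for atom in res:
                    atom.b_iso = UNMAPPED_BFACTOR
    mapped: dict[int, float] = {}
    for res in ch:
        pos = res.seqid.num - numbering_offset
        if pos in scores:
            mapped[pos] = scores[pos]
            b = clamp(scores[pos], lo, hi)
            for atom in res:
                atom.b_iso = b
    unmapped = sorted(set(scores) - set(mapped))
    if not mapped:
        raise ValidationError("no profile position maps onto the chosen chain")
    if pdb_out is not None:
        st.write_pdb(str(pdb_out))
    if attr_out is not None:
        with open(attr_out, "w") as fh:
            fh.write(f"# chain {chain} offset {numbering_offset}\n")
            for pos in sorted(mapped):
                fh.write(f"{pos + numbering_offset}\t{mapped[pos]!r}\n")
    return StructureAnnotation(
        structure_file=str(structure_file),
        chain=chain,
        numbering_offset=numbering_offset,
        mapped=mapped,
        unmapped=unmapped,
        pdb_out=pdb_out,
        attr_out=attr_out,
    )


def read_attribute_file(path: str) -> dict[int, float]:
    """Parse an attribute file back to residue-number -> score."""
    out = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            resnum, score = line.split("\t")
            out[int(resnum)] = float(score)
    return out


def extract_residue_set(
    structure_file: str,
    chain: str,
    residues: list[int] | None = None,
    contact_chain: str | None = None,
    cutoff: float = 4.5,
    numbering_offset: int = 0,
) -> set[int]:
    """Build a residue-position set, either explicitly or by contact rule.

    With ``residues`` the explicit list is returned unchanged (positions
    are already on the profile scale). With ``contact_chain``, residues of
    ``chain`` with any heavy atom within ``cutoff`` angstroms of a heavy
    atom of the second chain are selected and translated back to profile
    positions via the inverse offset.
    """
    if residues is not None:
        return set(int(r) for r in residues)
    if contact_chain is None:
        raise ValidationError("provide either an explicit residue list or a contact chain")
    if cutoff <= 0:
        raise ValidationError("contact cutoff must be positive")
    st, ch = _load_chain(structure_file, chain)
    other = st[0].find_chain(contact_chain)
    if other is None:
        raise ValidationError(f"contact chain {contact_chain!r} not found")
    other_xyz = np.array(
        [[a.pos.x, a.pos.y, a.pos.z] for res in other for a in res if a.element.name != "H"]
    )
    if other_xyz.size == 0:
        raise ValidationError(f"contact chain {contact_chain!r} has no heavy atoms")
    selected: set[int] = set()
    for res in ch:
        xyz = np.array([[a.pos.x, a.pos.y, a.pos.z] for a in res if a.element.name != "H"])
        if xyz.size == 0:
            continue
        d2 = ((xyz[:, None, :] - other_xyz[None, :, :]) ** 2).sum(axis=2)
        if d2.min() <= cutoff * cutoff:
            selected.add(res.seqid.num - numbering_offset)
    return selected
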