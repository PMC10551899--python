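import gemmi
import numpy as np
import pandas as pd
import pytest

from bifcscan.core import ReferenceProtein, VariantKey, codon_for
from bifcscan.counts import CountTable


@pytest.fixture(scope="session")
def tiny_ref() -> ReferenceProtein:
    aa = "MKTLIVGAWL"
    cds = "ATG" + "".join(codon_for(a) for a in aa[1:])
    return ReferenceProtein("tiny", aa, cds)


def make_count_table(ref, condition, counts, wt_count, discarded=None, replicate=""):
    """CountTable over the whole protein with uniform WT depth."""
    positions = frozenset(range(1, len(ref) + 1))
    counts = {ref.validate_variant(VariantKey(*k) if not isinstance(k, VariantKey) else k): c for k, c in counts.items()}
    discarded = discarded or {}
    return CountTable(
        condition=condition,
        reference=ref,
        counts=counts,
        wt_count=wt_count,
        discarded=discarded,
        total_reads=wt_count + sum(counts.values()) + sum(discarded.values()),
        positions=positions,
        wt_depth={p: wt_count for p in positions},
        replicate=replicate,
    ).validate()


def make_enrichment_frame(rows, selection="bifc", replicate="1"):
    """Minimal enrichment table from (position, wt, mut, log2_ratio, flag)."""
    df = pd.DataFrame(rows, columns=["position", "wt_aa", "mut_aa", "log2_ratio", "flag"])
    df["naive_freq"] = np.where(df["flag"] == "absent", 0.0, 1e-4)
    df.attrs.update(selection=selection, replicate=replicate)
    return df


def build_structure(residue_positions, chain_name="A", coords=None, second_chain=None):
    """Synthetic CA-only structure for mapping tests.

    ``coords``: optional map position -> (x, y, z); default spreads
    residues 10 A apart on x. ``second_chain``: (name, {pos: xyz}).
    """
    st = gemmi.Structure()
    st.name = "synthetic"
    model = gemmi.Model("1")

    def add_chain(name, positions, xyz_map):
        chain = gemmi.Chain(name)
        for pos in positions:
            res = gemmi.Residue()
            res.name = "ALA"
            res.seqid = gemmi.SeqId(pos, " ")
            atom = gemmi.Atom()
            atom.name = "CA"
            atom.element = gemmi.Element("C")
            x, y, z = xyz_map.get(pos, (10.0 * pos, 0.0, 0.0))
            atom.pos = gemmi.Position(x, y, z)
            atom.occ = 1.0
            atom.b_iso = 0.0
            res.add_atom(atom)
            chain.add_residue(res)
        model.add_chain(chain)

    add_chain(chain_name, residue_positions, coords or {})
    if second_chain is not None:
        name, xyz_map = second_chain
        add_chain(name, sorted(xyz_map), xyz_map)
    st.add_model(model)
    return st


@pytest.fixture
def write_structure(tmp_path):
    def _write(st, fname="toy.pdb"):
        path = tmp_path / fname
        st.setup_entities()
        st.write_pdb(str(path))
        return str(path)

    return _write
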