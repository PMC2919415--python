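"""Structure I/O and mass accounting.

Reads PDB files (via gemmi) into :class:`AtomicStructure`, including the
declared full sequence from SEQRES, the unit cell from CRYST1 and the
crystallographic symmetry operators from REMARK 290 SMTRY rows.  Computes
sequence/structure masses and the missing-mass fraction that drives the
modelling decision tree, and round-trips coarse-grained sphere models
through a pseudo-atom PDB convention (radius in the B-factor column, mass
in REMARK 251 rows).
"""
from __future__ import annotations

import re
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Data.IUPACData import protein_weights
from Bio.SeqUtils import molecular_weight

from .models import AtomicStructure, MassAccount, Sphere, SphereModel, SymOp, UnitCell

__all__ = [
    "read_structure",
    "read_fasta_sequences",
    "mass_account",
    "write_sphere_pdb",
    "read_sphere_pdb",
    "StructureError",
    "ConsistencyError",
]

WATER_MASS = 18.0153  # average mass of H2O, Da

# Monoisotopic residue masses are needed when `monoisotopic=True`; Biopython
# exposes only the average monomer table, so keep the standard monoisotopic
# residue (i.e. dehydrated) masses here.
_MONO_RESIDUE = {
    "A": 71.03711, "R": 156.10111, "N": 114.04293, "D": 115.02694,
    "C": 103.00919, "E": 129.04259, "Q": 128.05858, "G": 57.02146,
    "H": 137.05891, "I": 113.08406, "L": 113.08406, "K": 128.09496,
    "M": 131.04049, "F": 147.06841, "P": 97.05276, "S": 87.03203,
    "T": 101.04768, "W": 186.07931, "Y": 163.06333, "V": 99.06841,
}
_MONO_WATER = 18.010565


class StructureError(ValueError):
    """Raised for unreadable or empty structure files."""


class ConsistencyError(ValueError):
    """Raised when observed residues contradict the declared sequence."""


def residue_mass(one_letter: str, monoisotopic: bool = False) -> float:
    """Mass of one amino-acid residue (dehydrated, as polymerized), Da."""
    aa = one_letter.upper()
    if monoisotopic:
        if aa not in _MONO_RESIDUE:
            raise KeyError(f"unknown amino acid {one_letter!r}")
        return _MONO_RESIDUE[aa]
    if aa not in protein_weights:
        raise KeyError(f"unknown amino acid {one_letter!r}")
    return protein_weights[aa] - WATER_MASS


def sequence_mass(seq: str, monoisotopic: bool = False) -> float:
    """Mass of a polypeptide chain (residues + one water), Da."""
    if not seq:
        return 0.0
    if monoisotopic:
        return sum(_MONO_RESIDUE[a.upper()] for a in seq) + _MONO_WATER
    return float(molecular_weight(seq.upper(), seq_type="protein"))


_SMTRY = re.compile(
    r"REMARK 290\s+SMTRY(\d)\s+(\d+)\s+(-?[\d.]+)\s+(-?[\d.]+)\s+(-?[\d.]+)\s+(-?[\d.]+)"
)


def _parse_remark290(lines) -> list:
    """Parse REMARK 290 SMTRY rows (Cartesian Å convention) into SymOps."""
    rows: dict = {}
    for line in lines:
        m = _SMTRY.match(line)
        if not m:
            continue
        irow = int(m.group(1)) - 1
        iop = int(m.group(2))
        vals = [float(m.group(j)) for j in range(3, 7)]
        rows.setdefault(iop, {})[irow] = vals
    ops = []
    for iop in sorted(rows):
        got = rows[iop]
        if set(got) != {0, 1, 2}:
            raise StructureError(f"REMARK 290 operator {iop} has incomplete rows")
        R = np.array([got[i][:3] for i in range(3)])
        t = np.array([got[i][3] for i in range(3)])
        ops.append(SymOp.make(R, t, fractional=False))
    if ops and not any(op.is_identity() for op in ops):
        ops.insert(0, SymOp.identity())
    return ops


def _one_letter(resname: str) -> str:
    import gemmi

    info = gemmi.find_tabulated_residue(resname)
    if info is None:
        return "X"
    code = info.one_letter_code.upper()
    return code if code.isalpha() else "X"


def read_structure(path, first_model_only: bool = True) -> AtomicStructure:
    """Read a PDB file into an :class:`AtomicStructure`.

    The declared per-chain sequence comes from SEQRES when present,
    otherwise from the observed residues.  Alternate locations are resolved
    by keeping the highest-occupancy conformer; for NMR entries only the
    first model is used.
    """
    import gemmi

    path = Path(path)
    if not path.exists():
        raise StructureError(f"no such file: {path}")
    try:
        st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except (RuntimeError, ValueError) as exc:
        raise StructureError(f"cannot parse {path}: {exc}") from exc

    # Declared sequences from SEQRES (gemmi entities), before any editing.
    chains_seq: dict = {}
    for ent in st.entities:
        if not ent.full_sequence:
            continue
        seq = "".join(
            _one_letter(gemmi.Entity.first_mon(m)) for m in ent.full_sequence
        )
        for sub in ent.subchains:
            chains_seq.setdefault(sub.rstrip("xX"), seq)
        if ent.name and ent.name not in chains_seq:
            chains_seq[ent.name] = seq

    cell = None
    if st.cell and st.cell.a > 1.0:
        cell = UnitCell(
            st.cell.a, st.cell.b, st.cell.c, st.cell.alpha, st.cell.beta, st.cell.gamma
        )

    sym_ops = _parse_remark290(getattr(st, "raw_remarks", []) or []) or None

    if len(st) == 0:
        raise StructureError(f"{path}: no coordinate models")
    model = st[0]

    elements, atom_names, res_names, res_seq, icodes, chain_ids, xyz = (
        [], [], [], [], [], [], []
    )
    # altloc resolution: keep highest occupancy per (chain, resid, icode, atom)
    best: dict = {}
    order: list = []
    for chain in model:
        for res in chain:
            for atom in res:
                key = (chain.name, res.seqid.num, res.seqid.icode.strip(), atom.name)
                occ = atom.occ if atom.occ > 0 else 1.0
                if key not in best:
                    order.append(key)
                    best[key] = (occ, res.name, atom)
                elif occ > best[key][0]:
                    best[key] = (occ, res.name, atom)
    for key in order:
        ch, rs, ic, aname = key
        _, rname, atom = best[key]
        elements.append(atom.element.name if atom.element else "C")
        atom_names.append(aname)
        res_names.append(rname)
        res_seq.append(rs)
        icodes.append(ic)
        chain_ids.append(ch)
        xyz.append([atom.pos.x, atom.pos.y, atom.pos.z])

    if not xyz:
        raise StructureError(f"{path}: structure contains no atoms")

    struct = AtomicStructure(
        elements=elements,
        atom_names=atom_names,
        res_names=res_names,
        res_seq=np.array(res_seq, dtype=int),
        icodes=icodes,
        chain_ids=chain_ids,
        coords=np.array(xyz, dtype=float),
        chains={},
        cell=cell,
        sym_ops=sym_ops,
        source=str(path),
    )

    # Fill declared sequences: SEQRES if available, else observed residues.
    observed_chains = sorted(set(chain_ids), key=chain_ids.index)
    names = struct.residue_names()
    for ch in observed_chains:
        if ch in chains_seq:
            struct.chains[ch] = chains_seq[ch]
        else:
            seq = "".join(
                _one_letter(names[k]) for k in struct.residue_keys() if k[0] == ch
            )
            struct.chains[ch] = seq
    return struct


def read_fasta_sequences(path) -> dict:
    """Read a FASTA file into {chain_id: sequence}; record ids are chain ids."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def mass_account(
    structure: AtomicStructure,
    full_sequence: dict | None = None,
    monoisotopic: bool = False,
) -> MassAccount:
    """Account for the mass present in vs. absent from a structure.

    ``full_sequence`` (chain id -> one-letter sequence) overrides the
    structure's declared sequences; this is how a full-length biological
    sequence is supplied when the crystallized construct's SEQRES is itself
    truncated.  A residue counts as present iff it has at least one observed
    heavy atom; observed residues must match the declared sequence at their
    residue number (1-based position in the sequence).
    """
    declared = dict(structure.chains)
    if full_sequence:
        declared.update({k: v.upper() for k, v in full_sequence.items()})
    if not declared:
        raise ConsistencyError("no declared sequence for any chain")

    heavy = structure.heavy_mask()
    names = structure.residue_names()
    observed: dict = {}
    for i, (ch, rs, ic) in enumerate(
        zip(structure.chain_ids, structure.res_seq, structure.icodes)
    ):
        if heavy[i]:
            observed.setdefault((ch, int(rs), ic), names[(ch, int(rs), ic)])

    m_full = 0.0
    m_present = 0.0
    missing_segments = []
    for ch in sorted(declared):
        seq = declared[ch]
        if not seq:
            continue
        m_full += sequence_mass(seq, monoisotopic)
        obs_pos = set()
        for (och, rs, ic), rname in observed.items():
            if och != ch:
                continue
            if not (1 <= rs <= len(seq)):
                raise ConsistencyError(
                    f"chain {ch}: observed residue {rs} outside declared "
                    f"sequence of length {len(seq)}"
                )
            letter = _one_letter(rname)
            if letter != "X" and seq[rs - 1] != letter:
                raise ConsistencyError(
                    f"chain {ch} residue {rs}: observed {letter} but declared "
                    f"{seq[rs - 1]}"
                )
            obs_pos.add(rs)
        if obs_pos:
            m_present += (
                sum(residue_mass(seq[p - 1], monoisotopic) for p in obs_pos)
                + (_MONO_WATER if monoisotopic else WATER_MASS)
            )
        # contiguous runs of declared-but-absent residues
        pos = 1
        while pos <= len(seq):
            if pos not in obs_pos:
                start = pos
                while pos <= len(seq) and pos not in obs_pos:
                    pos += 1
                missing_segments.append((ch, start, pos - 1))
            else:
                pos += 1

    if m_present <= 0:
        raise ConsistencyError("no observed residues in any declared chain")
    f_missing = (m_full - m_present) / m_full
    # numerical guard: a fully observed chain can give a tiny negative value
    f_missing = max(f_missing, 0.0)
    m_present = min(m_present, m_full)
    return MassAccount(
        m_present=m_present,
        m_full=m_full,
        f_missing=f_missing,
        missing_segments=tuple(missing_segments),
    )


# --- sphere-model pseudo-atom PDB convention ------------------------------
#
# One HETATM per sphere (atom name "SPH", residue "SPH", element C), radius
# in the B-factor column (%6.2f), and one "REMARK 251 SPHERE" row per sphere
# carrying label, kind and mass at full precision.


def write_sphere_pdb(model: SphereModel, path) -> None:
    """Write a sphere model as a pseudo-atom PDB file."""
    if len(model) == 0:
        raise ValueError("cannot write an empty sphere model")
    lines = ["REMARK 250 COARSE-GRAINED SPHERE MODEL"]
    if model.provenance:
        lines.append(f"REMARK 250 PROVENANCE {model.provenance}")
    for i, s in enumerate(model.spheres, start=1):
        if s.radius >= 1000.0:
            raise ValueError(
                f"sphere {s.label!r}: radius {s.radius:.2f} Å exceeds the "
                "B-factor column precision (< 1000)"
            )
        lines.append(
            f"REMARK 251 SPHERE {i:4d} LABEL {s.label} KIND {s.kind} "
            f"MASS {s.mass:.4f}"
        )
    for i, s in enumerate(model.spheres, start=1):
        x, y, z = s.center
        lines.append(
            f"HETATM{i:5d}  SPH SPH A{i:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{s.radius:6.2f}           C"
        )
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def read_sphere_pdb(path) -> SphereModel:
    """Read a pseudo-atom PDB written by :func:`write_sphere_pdb`."""
    meta: dict = {}
    provenance = ""
    spheres = []
    order = []
    for line in Path(path).read_text().splitlines():
        if line.startswith("REMARK 250 PROVENANCE"):
            provenance = line[len("REMARK 250 PROVENANCE ") :].strip()
        elif line.startswith("REMARK 251 SPHERE"):
            m = re.match(
                r"REMARK 251 SPHERE\s+(\d+)\s+LABEL (.*) KIND (\S+) MASS ([\d.eE+-]+)",
                line,
            )
            if not m:
                raise StructureError(f"malformed sphere remark: {line!r}")
            meta[int(m.group(1))] = (m.group(2), m.group(3), float(m.group(4)))
        elif line.startswith("HETATM"):
            serial = int(line[6:11])
            x = float(line[30:38])
            y = float(line[38:46])
            z = float(line[46:54])
            radius = float(line[60:66])
            order.append((serial, (x, y, z), radius))
    if not order:
        raise StructureError(f"{path}: no sphere pseudo-atoms found")
    for serial, center, radius in order:
        label, kind, mass = meta.get(serial, (f"sphere{serial}", "domain", 1.0))
        spheres.append(
            Sphere(label=label, center=center, radius=radius, mass=mass, kind=kind)
        )
    return SphereModel(spheres=spheres, provenance=provenance)
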