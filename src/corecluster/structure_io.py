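"""Reading, trimming, filtering and identity-clustering of protein chains.

Structures are reduced to their C-alpha trace: one :class:`ResidueRecord`
per residue that has a C-alpha atom.  Curation follows the rules commonly
used when assembling a structure dataset for clan-wide comparison: a
minimum chain length (so both catalytic sub-domains are present), a cap on
missing residues, a resolution cut-off, and greedy clustering at a maximum
pairwise sequence identity so that near-duplicates do not dominate.

Author numbering (``res_seq`` + insertion code) is preserved from the
input file; all in-memory positions elsewhere in the package are 0-based
contiguous indices into ``StructureModel.residues``.
"""

from __future__ import annotations

import dataclasses
import os
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import gemmi
import numpy as np
import pandas as pd
from Bio.Align import PairwiseAligner, substitution_matrices

__all__ = [
    "ParseError",
    "ResidueRecord",
    "StructureModel",
    "FilterConfig",
    "read_structure",
    "write_structure",
    "trim_to_range",
    "filter_dataset",
    "pairwise_identity",
    "identity_cluster",
    "write_manifest",
]

STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"

_THREE_LETTER = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE",
    "G": "GLY", "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU",
    "M": "MET", "N": "ASN", "P": "PRO", "Q": "GLN", "R": "ARG",
    "S": "SER", "T": "THR", "V": "VAL", "W": "TRP", "Y": "TYR",
    "X": "UNK",
}


class ParseError(ValueError):
    """Raised when a structure file cannot be turned into a usable model."""


@dataclass(frozen=True)
class ResidueRecord:
    """One residue of a C-alpha trace, in author numbering."""

    chain_id: str
    res_seq: int
    icode: str  # insertion code, "" when absent
    aa: str  # one-letter code, 'X' for nonstandard
    ca_xyz: tuple[float, float, float]
    b_factor: float | None = None

    def __post_init__(self) -> None:
        if self.aa not in STANDARD_AA and self.aa != "X":
            raise ValueError(f"invalid amino-acid letter {self.aa!r}")
        if not all(np.isfinite(self.ca_xyz)):
            raise ValueError("non-finite C-alpha coordinate")


@dataclass
class StructureModel:
    """A single protein chain reduced to its C-alpha trace.

    ``n_missing`` counts residues that are declared (SEQRES) or implied
    (author-numbering gaps) but have no C-alpha coordinate.
    ``resolution`` is in Angstrom, ``None`` for structures without a
    crystallographic resolution (e.g. NMR models).
    """

    model_id: str
    residues: list[ResidueRecord]
    resolution: float | None = None
    n_missing: int = 0
    family_label: str = ""
    subfamily_label: str = ""

    def __post_init__(self) -> None:
        if len(self.residues) < 1:
            raise ValueError(f"{self.model_id}: empty structure")
        seen = set()
        for r in self.residues:
            key = (r.res_seq, r.icode)
            if key in seen:
                raise ValueError(f"{self.model_id}: duplicate residue {key}")
            seen.add(key)

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def sequence(self) -> str:
        return "".join(r.aa for r in self.residues)

    @property
    def ca_coords(self) -> np.ndarray:
        """(N, 3) float array of C-alpha coordinates, chain order."""
        return np.array([r.ca_xyz for r in self.residues], dtype=float)


@dataclass(frozen=True)
class FilterConfig:
    """Dataset curation thresholds.

    Defaults reproduce the standard clan-curation rules: chains of at
    least 138 modeled residues (large enough to hold both beta-barrel
    domains), at most 10 missing residues, resolution no worse than
    4.0 A, and a 70% ceiling on pairwise sequence identity.
    """

    min_length: int = 138
    max_missing: int = 10
    max_resolution: float = 4.0
    max_identity: float = 0.70

    def __post_init__(self) -> None:
        if self.min_length < 1:
            raise ValueError("min_length must be >= 1")
        if not (0.0 < self.max_identity <= 1.0):
            raise ValueError("max_identity must be in (0, 1]")


def _one_letter(resname: str) -> str:
    info = gemmi.find_tabulated_residue(resname)
    if info is None:
        return "X"
    code = info.one_letter_code.upper()
    return code if code in STANDARD_AA else "X"


def read_structure(path: str | os.PathLike, chain: str, model_id: str | None = None) -> StructureModel:
    """Read one chain of a PDB file into a C-alpha trace model.

    For altloc duplicates the highest-occupancy C-alpha is kept (ties:
    first encountered).  HETATM records and waters are ignored.  Missing
    residues are counted from SEQRES when present, otherwise from gaps in
    author numbering.

    Raises
    ------
    ParseError
        If the file is missing, the chain is absent, or the chain has no
        C-alpha atoms.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise ParseError(f"structure file not found: {path}")
    st = gemmi.read_structure(path, format=gemmi.CoorFormat.Pdb)
    st.setup_entities()
    if len(st) == 0:
        raise ParseError(f"{path}: no models")
    gmodel = st[0]
    gchain = gmodel.find_chain(chain)
    if gchain is None:
        raise ParseError(f"{path}: chain {chain!r} not found")

    records: list[ResidueRecord] = []
    for res in gchain:
        if res.het_flag != "A" or res.is_water():
            continue
        best = None
        for atom in res:
            if atom.name != "CA":
                continue
            if best is None or atom.occ > best.occ:
                best = atom
        if best is None:
            continue
        records.append(
            ResidueRecord(
                chain_id=chain,
                res_seq=res.seqid.num,
                icode=res.seqid.icode.strip(),
                aa=_one_letter(res.name),
                ca_xyz=(best.pos.x, best.pos.y, best.pos.z),
                b_factor=best.b_iso,
            )
        )
    if not records:
        raise ParseError(f"{path}: chain {chain!r} has no C-alpha atoms")

    seqres_len = 0
    for ent in st.entities:
        if ent.entity_type == gemmi.EntityType.Polymer and chain in ent.subchains:
            seqres_len = max(seqres_len, len(ent.full_sequence))
    # gemmi maps chains to subchains via setup_entities; fall back to name match
    if seqres_len == 0:
        for ent in st.entities:
            if chain in ent.subchains or any(s.startswith(chain) for s in ent.subchains):
                seqres_len = max(seqres_len, len(ent.full_sequence))

    if seqres_len > 0:
        n_missing = max(0, seqres_len - len(records))
    else:
        gaps = 0
        for prev, cur in zip(records, records[1:]):
            if cur.res_seq > prev.res_seq + 1:
                gaps += cur.res_seq - prev.res_seq - 1
        n_missing = gaps

    resolution = st.resolution if st.resolution and st.resolution > 0 else None
    return StructureModel(
        model_id=model_id if model_id is not None else f"{st.name or os.path.basename(path)}_{chain}",
        residues=records,
        resolution=resolution,
        n_missing=n_missing,
    )


def write_structure(model: StructureModel, path: str | os.PathLike) -> None:
    """Write a C-alpha trace model as fixed-column PDB ATOM records."""
    st = gemmi.Structure()
    st.name = model.model_id[:4] if model.model_id else "XXXX"
    if model.resolution is not None:
        st.resolution = model.resolution
    gmodel = gemmi.Model("1")
    chain = gemmi.Chain(model.residues[0].chain_id or "A")
    for rec in model.residues:
        res = gemmi.Residue()
        res.name = _THREE_LETTER[rec.aa]
        res.seqid = gemmi.SeqId(rec.res_seq, rec.icode if rec.icode else " ")
        atom = gemmi.Atom()
        atom.name = "CA"
        atom.element = gemmi.Element("C")
        atom.pos = gemmi.Position(*rec.ca_xyz)
        atom.occ = 1.0
        atom.b_iso = rec.b_factor if rec.b_factor is not None else 0.0
        res.add_atom(atom)
        chain.add_residue(res)
    gmodel.add_chain(chain)
    st.add_model(gmodel)
    st.write_pdb(os.fspath(path))


def trim_to_range(model: StructureModel, first: int, last: int) -> StructureModel:
    """Keep residues with ``first <= res_seq <= last`` (author numbering).

    Insertion-code residues share their base number, so a range that ends
    at 20 keeps 20 and 20A alike.  Used to cut multi-domain chains down to
    the protease domain before alignment.
    """
    if first > last:
        raise ValueError(f"invalid range: first {first} > last {last}")
    kept = [r for r in model.residues if first <= r.res_seq <= last]
    if not kept:
        raise ValueError(f"{model.model_id}: trim range {first}..{last} leaves no residues")
    return dataclasses.replace(model, residues=kept)


def filter_dataset(
    models: Sequence[StructureModel], cfg: FilterConfig | None = None
) -> tuple[list[StructureModel], pd.DataFrame]:
    """Apply length / missing-residue / resolution filters.

    Returns the kept models plus a per-model report naming every failed
    rule (``min_length``, ``max_missing``, ``max_resolution``).  Unknown
    resolution passes the resolution rule: the filter targets poor
    crystallographic models, not structures solved by other methods.
    """
    if cfg is None:
        cfg = FilterConfig()
    kept: list[StructureModel] = []
    rows = []
    for m in models:
        failed = []
        if len(m) < cfg.min_length:
            failed.append("min_length")
        if m.n_missing > cfg.max_missing:
            failed.append("max_missing")
        if m.resolution is not None and m.resolution > cfg.max_resolution:
            failed.append("max_resolution")
        if not failed:
            kept.append(m)
        rows.append(
            {
                "model_id": m.model_id,
                "length": len(m),
                "resolution": m.resolution,
                "n_missing": m.n_missing,
                "kept": not failed,
                "failed_rules": ",".join(failed),
            }
        )
    report = pd.DataFrame(rows, columns=["model_id", "length", "resolution", "n_missing", "kept", "failed_rules"])
    return kept, report


def _make_aligner(matrix: str = "BLOSUM62", gap_open: float = 11.0, gap_extend: float = 1.0) -> PairwiseAligner:
    aligner = PairwiseAligner(mode="local")
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    aligner.open_gap_score = -abs(gap_open)
    aligner.extend_gap_score = -abs(gap_extend)
    return aligner


def pairwise_identity(
    seq_a: str,
    seq_b: str,
    *,
    matrix: str = "BLOSUM62",
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
) -> float:
    """Smith-Waterman local-alignment identity between two sequences.

    Identity is identical aligned positions divided by all aligned
    columns (gaps included) of the optimal local alignment; a zero-score
    alignment yields identity 0.  Symmetric by construction.
    """
    if not seq_a or not seq_b:
        raise ValueError("empty sequence")
    aligner = _make_aligner(matrix, gap_open, gap_extend)
    if aligner.score(seq_a, seq_b) <= 0:
        return 0.0
    aln = aligner.align(seq_a, seq_b)[0]
    c = aln.counts()
    columns = c.identities + c.mismatches + c.internal_gaps
    if columns == 0:
        return 0.0
    return c.identities / columns


def identity_cluster(
    models: Sequence[StructureModel], max_identity: float = 0.70
) -> list[StructureModel]:
    """Greedy identity clustering; returns one representative per cluster.

    Models are visited in order of decreasing length (ties broken by
    lexicographic model_id, mimicking CD-hit's longest-first strategy).
    A model joins the first existing cluster whose representative shares
    identity strictly above ``max_identity`` (exact sequence duplicates
    always join, so ``max_identity=1.0`` removes only duplicates);
    otherwise it founds a new cluster and becomes its representative.
    """
    order = sorted(models, key=lambda m: (-len(m), m.model_id))
    reps: list[StructureModel] = []
    for m in order:
        for rep in reps:
            if (
                m.sequence == rep.sequence
                or pairwise_identity(m.sequence, rep.sequence) > max_identity
            ):
                break
        else:
            reps.append(m)
    return reps


def write_manifest(report: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write the filter report as a TSV manifest with stable formatting."""
    df = report.copy()
    df["resolution"] = df["resolution"].map(lambda r: "" if r is None or pd.isna(r) else f"{r:.2f}")
    df["kept"] = df["kept"].map(lambda k: "yes" if k else "no")
    df.to_csv(os.fspath(path), sep="\t", index=False)


def read_chain_list(path: str | os.PathLike) -> list[tuple[str, str]]:
    """Read a two-column (file, chain) TSV used by the CLI."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            out.append((parts[0], parts[1] if len(parts) > 1 else "A"))
    return out
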