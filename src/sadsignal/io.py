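"""File formats: the CSV reflection dialect, MTZ, PDB models, JSON reports.

CSV reflection dialect (fully specified so independent implementations
interoperate): UTF-8, '.' decimal separator, one reflection per row, header

    h,k,l,d,centric,Fplus,sigFplus,Fminus,sigFminus

with integer Miller indices, d in Angstrom, centric as True/False, and
amplitudes/uncertainties in a common arbitrary scale.
"""

from __future__ import annotations

import dataclasses
import json

import numpy as np
import pandas as pd

from .crystal import AtomSite, SymmetryOps, UnitCell
from .errors import FormatError
from .scattering import ScatteringModel
from .simulate import REFLECTION_COLUMNS, SimulationConfig
from .structure_factors import CrystalModel

__all__ = [
    "read_reflections_csv",
    "write_reflections_csv",
    "read_reflections_mtz",
    "write_reflections_mtz",
    "read_reflections",
    "write_model_pdb",
    "read_model_pdb",
    "write_report_json",
    "load_config_json",
    "save_config_json",
]


def _validate_columns(df: pd.DataFrame, path) -> pd.DataFrame:
    for col in REFLECTION_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    dup = df.duplicated(subset=["h", "k", "l"])
    if dup.any():
        raise FormatError(f"{path}: duplicate Miller indices (first: "
                          f"{tuple(df.loc[dup.idxmax(), ['h', 'k', 'l']])}); merge first")
    df = df[REFLECTION_COLUMNS].copy()
    df[["h", "k", "l"]] = df[["h", "k", "l"]].astype(int)
    df["centric"] = df["centric"].astype(bool)
    return df


def read_reflections_csv(path) -> pd.DataFrame:
    """Read the documented CSV reflection dialect."""
    return _validate_columns(pd.read_csv(path), path)


def write_reflections_csv(reflections: pd.DataFrame, path) -> None:
    reflections[REFLECTION_COLUMNS].to_csv(path, index=False)


def write_reflections_mtz(reflections: pd.DataFrame, cell: UnitCell, path) -> None:
    """Write Bijvoet amplitude pairs to MTZ (P1 symmetry record)."""
    import gemmi

    mtz = gemmi.Mtz(with_base=True)
    mtz.spacegroup = gemmi.SpaceGroup("P1")
    mtz.set_cell_for_all(gemmi.UnitCell(cell.a, cell.b, cell.c, cell.alpha, cell.beta, cell.gamma))
    mtz.add_dataset("sadsignal")
    for name, typ in [("F(+)", "G"), ("SIGF(+)", "L"), ("F(-)", "G"), ("SIGF(-)", "L")]:
        mtz.add_column(name, typ)
    data = np.column_stack(
        [
            reflections[["h", "k", "l"]].to_numpy(dtype=float),
            reflections[["Fplus", "sigFplus", "Fminus", "sigFminus"]].to_numpy(dtype=float),
        ]
    )
    mtz.set_data(data)
    mtz.write_to_file(str(path))


def read_reflections_mtz(path, sym: SymmetryOps | None = None) -> tuple[pd.DataFrame, UnitCell]:
    """Read Bijvoet pairs from MTZ; centric flags recomputed from ``sym``.

    Returns the reflection table in the CSV dialect plus the unit cell.
    """
    import gemmi

    mtz = gemmi.Mtz()
    try:
        mtz = gemmi.read_mtz_file(str(path))
    except (RuntimeError, OSError) as exc:
        raise FormatError(f"{path}: {exc}") from exc
    cell = UnitCell(mtz.cell.a, mtz.cell.b, mtz.cell.c, mtz.cell.alpha, mtz.cell.beta, mtz.cell.gamma)
    cols = {c.label: np.asarray(c) for c in mtz.columns}
    for need in ["H", "K", "L", "F(+)", "SIGF(+)", "F(-)", "SIGF(-)"]:
        if need not in cols:
            raise FormatError(f"{path}: missing required MTZ column {need!r}")
    hkl = np.column_stack([cols["H"], cols["K"], cols["L"]]).astype(int)
    sym = sym or SymmetryOps.p1()
    equivs = np.einsum("nj,rji->rni", hkl, sym.rotations)
    centric = np.any(np.all(equivs == -hkl[None], axis=2), axis=0)
    df = pd.DataFrame(
        {
            "h": hkl[:, 0],
            "k": hkl[:, 1],
            "l": hkl[:, 2],
            "d": cell.d_spacing(hkl),
            "centric": centric,
            "Fplus": cols["F(+)"],
            "sigFplus": cols["SIGF(+)"],
            "Fminus": cols["F(-)"],
            "sigFminus": cols["SIGF(-)"],
        }
    )
    return df, cell


def read_reflections(path, fmt: str | None = None, sym: SymmetryOps | None = None) -> pd.DataFrame:
    """Read reflections from CSV or MTZ (by extension unless ``fmt`` given)."""
    fmt = fmt or ("mtz" if str(path).lower().endswith(".mtz") else "csv")
    if fmt == "mtz":
        return read_reflections_mtz(path, sym)[0]
    return read_reflections_csv(path)


def write_model_pdb(model: CrystalModel, path) -> None:
    """Write the crystal model as a PDB file (CRYST1 + HETATM records).

    Substructure atoms keep their element; the symmetry record is written as
    P1 (operators beyond P1 travel via configuration, not the PDB header).
    """
    import gemmi

    st = gemmi.Structure()
    st.cell = gemmi.UnitCell(
        model.cell.a, model.cell.b, model.cell.c, model.cell.alpha, model.cell.beta, model.cell.gamma
    )
    st.spacegroup_hm = "P 1"
    gmodel = gemmi.Model("1")
    chain = gemmi.Chain("A")
    groups = [
        ("ORD", model.ordinary_atoms),
        ("SUB", model.substructure_atoms),
        ("MIN", model.minor_sites),
    ]
    serial = 0
    for resname, atoms in groups:
        for site in atoms:
            serial += 1
            res = gemmi.Residue()
            res.name = resname
            res.seqid = gemmi.SeqId(serial, " ")
            res.het_flag = "H"
            atom = gemmi.Atom()
            atom.name = site.element.upper()
            atom.element = gemmi.Element(site.element.capitalize())
            atom.occ = site.occupancy
            atom.b_iso = site.b_iso
            atom.pos = st.cell.orthogonalize(gemmi.Fractional(*site.frac))
            res.add_atom(atom)
            chain.add_residue(res)
    gmodel.add_chain(chain)
    st.add_model(gmodel)
    st.setup_entities()
    st.write_pdb(str(path))


def read_model_pdb(
    path,
    substructure_elements: set[str] | None = None,
    minor_elements: set[str] | None = None,
    scattering: ScatteringModel | None = None,
    sym: SymmetryOps | None = None,
) -> CrystalModel:
    """Read a crystal model from PDB: CRYST1 for the cell, ATOM/HETATM for sites.

    Atoms whose element is in ``substructure_elements`` (default {'SE'})
    become the anomalous substructure; symmetry operators are supplied via
    ``sym`` (default P1), never read from the header.
    """
    import gemmi

    substructure_elements = {e.upper() for e in (substructure_elements or {"SE"})}
    minor_elements = {e.upper() for e in (minor_elements or set())}
    st = gemmi.read_structure(str(path))
    if st.cell.volume <= 0:
        raise FormatError(f"{path}: missing or degenerate CRYST1 record")
    cell = UnitCell(st.cell.a, st.cell.b, st.cell.c, st.cell.alpha, st.cell.beta, st.cell.gamma)
    ordinary, substructure, minor = [], [], []
    for gmodel in st:
        for chain in gmodel:
            for res in chain:
                for atom in res:
                    frac = st.cell.fractionalize(atom.pos)
                    site = AtomSite(
                        element=atom.element.name.upper(),
                        frac=(frac.x, frac.y, frac.z),
                        occupancy=atom.occ,
                        b_iso=atom.b_iso,
                    )
                    if site.element in substructure_elements:
                        substructure.append(site)
                    elif site.element in minor_elements:
                        minor.append(site)
                    else:
                        ordinary.append(site)
        break  # first model only
    return CrystalModel(
        cell=cell,
        sym=sym or SymmetryOps.p1(),
        ordinary_atoms=ordinary,
        substructure_atoms=substructure,
        minor_sites=minor,
        scattering=scattering or ScatteringModel(),
    )


def write_report_json(report, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(report.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")


def save_config_json(config: SimulationConfig, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(dataclasses.asdict(config), fh, indent=2)


def load_config_json(path) -> SimulationConfig:
    with open(path, encoding="utf-8") as fh:
        raw = json.load(fh)
    for key in ("cell", "b_range_ordinary", "b_range_substructure"):
        if key in raw and raw[key] is not None:
            raw[key] = tuple(raw[key])
    return SimulationConfig(**raw)
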