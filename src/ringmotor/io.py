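"""CSV/JSON/PDB interchange for curves, datasets, trajectories and loops.

Tabular outputs are plain CSV with a JSON sidecar of generation or model
metadata (including seeds) so every file is self-describing.  Pore-loop point
sets round-trip through CSV and through a minimal standard coordinate file
(one pseudo-atom per point, written with gemmi) for interoperability with
structure viewers.
"""

from __future__ import annotations

import json
from pathlib import Path

import gemmi
import numpy as np
import pandas as pd

from .ring_model import ActivityCurve
from .synthetic import DopingDataset, PoreLoopSet

__all__ = [
    "write_activity_curve",
    "write_doping_dataset",
    "read_doping_dataset",
    "write_pore_loops_csv",
    "read_pore_loops_csv",
    "write_pore_loops_pdb",
    "read_pore_loops_structure",
    "write_trajectory",
    "write_fit_result",
]


def _sidecar(path: Path, metadata: dict) -> None:
    side = path.with_suffix(path.suffix + ".json")
    side.write_text(json.dumps(metadata, indent=2, default=str))


def write_activity_curve(curve: ActivityCurve, path) -> Path:
    path = Path(path)
    curve.to_frame().to_csv(path, index=False)
    _sidecar(path, {"label": curve.label, **curve.metadata})
    return path


def write_doping_dataset(dataset: DopingDataset, path) -> Path:
    path = Path(path)
    dataset.data.to_csv(path, index=False)
    _sidecar(path, {"assay_kind": dataset.assay_kind, **dataset.metadata})
    return path


def read_doping_dataset(path, assay_kind: str = "atpase") -> DopingDataset:
    path = Path(path)
    data = pd.read_csv(path)
    meta = {}
    side = path.with_suffix(path.suffix + ".json")
    if side.exists():
        meta = json.loads(side.read_text())
        assay_kind = meta.pop("assay_kind", assay_kind)
    return DopingDataset(assay_kind=assay_kind, data=data, metadata=meta)


def write_pore_loops_csv(loops: PoreLoopSet, path) -> Path:
    path = Path(path)
    loops.points.to_csv(path, index=False)
    _sidecar(path, {"seam_index": loops.seam_index})
    return path


def read_pore_loops_csv(path) -> PoreLoopSet:
    path = Path(path)
    seam = None
    side = path.with_suffix(path.suffix + ".json")
    if side.exists():
        seam = json.loads(side.read_text()).get("seam_index")
    return PoreLoopSet(points=pd.read_csv(path), seam_index=seam)


def write_pore_loops_pdb(loops: PoreLoopSet, path) -> Path:
    """Write one CA pseudo-atom per pore-loop point (synthetic coordinates).

    Protomers become chains A, B, ...; each loop label becomes one residue
    so the file is viewable in any structure viewer.
    """
    path = Path(path)
    st = gemmi.Structure()
    st.name = "pore-loop pseudo-atoms"
    model = gemmi.Model("1")
    labels = list(dict.fromkeys(loops.points["loop"]))
    for protomer, grp in loops.points.groupby("protomer", sort=True):
        chain = gemmi.Chain(chr(ord("A") + int(protomer) % 26))
        for _, row in grp.iterrows():
            res = gemmi.Residue()
            res.name = "GLY"
            res.seqid = gemmi.SeqId(labels.index(row["loop"]) + 1, " ")
            atom = gemmi.Atom()
            atom.name = "CA"
            atom.element = gemmi.Element("C")
            atom.pos = gemmi.Position(row["x"], row["y"], row["z"])
            res.add_atom(atom)
            chain.add_residue(res)
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))
    return path


def read_pore_loops_structure(path, loops: dict[str, list[int]],
                              chains: list[str] | None = None) -> PoreLoopSet:
    """Extract labeled pore-loop points from a PDB/mmCIF file.

    ``loops`` maps a loop label to the residue numbers whose CA atoms define
    it; one point (the CA centroid of those residues) is produced per
    (chain, loop).  ``chains`` gives the protomer cyclic order; default is
    the file's chain order.
    """
    st = gemmi.read_structure(str(path))
    model = st[0]
    if chains is None:
        chains = [ch.name for ch in model]
    rows = []
    for idx, chain_name in enumerate(chains):
        chain = model[chain_name]
        for label, resnums in loops.items():
            coords = []
            for res in chain:
                if res.seqid.num in resnums:
                    for atom in res:
                        if atom.name == "CA":
                            coords.append([atom.pos.x, atom.pos.y, atom.pos.z])
            if not coords:
                raise ValueError(
                    f"no CA atoms for loop {label!r} in chain {chain_name}"
                )
            c = np.mean(coords, axis=0)
            rows.append((idx, label, c[0], c[1], c[2]))
    return PoreLoopSet(
        points=pd.DataFrame(rows, columns=["protomer", "loop", "x", "y", "z"])
    )


def write_trajectory(traj, path) -> Path:
    path = Path(path)
    traj.to_frame().to_csv(path, index=False)
    _sidecar(path, {
        "rng_seed": traj.rng_seed,
        "t_end": traj.t_end,
        "n_transitions": traj.n_transitions,
        "substrates_completed": traj.substrates_completed,
    })
    return path


def write_fit_result(fit, path) -> Path:
    path = Path(path)
    payload = {
        "rss_by_m": {str(m): v for m, v in fit.rss_by_m.items()},
        "best_m": fit.best_m,
        "k_escape_hat": fit.k_escape_hat,
        "bootstrap_selection_frequency":
            {str(m): v for m, v in fit.bootstrap_ci_m.items()},
        "n_protomers": fit.n_protomers,
    }
    path.write_text(json.dumps(payload, indent=2))
    return path
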