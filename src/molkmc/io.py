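"""Reading and writing coordinate frames (XYZ and multi-MODEL PDB).

Thin wrappers over MDAnalysis. Formats are selected by file extension;
round trips are lossless to format precision (PDB prints three decimals).
"""

from __future__ import annotations

import os
import warnings

import numpy as np

from .ensemble import Ensemble, Frame
from .errors import ShapeError
from .topology import Topology


def _format_of(path) -> str:
    ext = os.path.splitext(str(path))[1].lower()
    if ext in (".xyz", ".pdb"):
        return ext[1:]
    raise ShapeError(f"unsupported coordinate format {ext!r} (use .xyz or .pdb)")


def write_frames(e: Ensemble, path) -> None:
    """Write all frames of an ensemble to an XYZ or multi-MODEL PDB file."""
    import MDAnalysis as mda

    fmt = _format_of(path)
    t = e.topology
    n = t.n_atoms
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe.empty(n, trajectory=True)
        u.add_TopologyAttr("elements", [a.element for a in t.atoms])
        u.add_TopologyAttr("names", [a.element for a in t.atoms])
        if fmt == "pdb":
            u.add_TopologyAttr("resnames", [t.atoms[0].residue_name if n else "MOL"])
            u.add_TopologyAttr("resids", [1])
        with mda.Writer(str(path), n_atoms=n, multiframe=True) as w:
            for frame in e.frames:
                u.atoms.positions = np.asarray(frame.positions, dtype=np.float32)
                w.write(u.atoms)


def read_frames(path, t: Topology) -> Ensemble:
    """Read frames from an XYZ or multi-MODEL PDB file for topology ``t``."""
    import MDAnalysis as mda

    _format_of(path)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(str(path))
        if len(u.atoms) != t.n_atoms:
            raise ShapeError(
                f"file has {len(u.atoms)} atoms, topology has {t.n_atoms}"
            )
        frames = [
            Frame(positions=np.asarray(u.atoms.positions, dtype=float), time=float(i))
            for i, _ in enumerate(u.trajectory)
        ]
    return Ensemble(topology=t, frames=frames, provenance=f"file:{path}")
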