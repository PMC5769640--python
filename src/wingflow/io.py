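"""File output: force CSV series, VTK legacy snapshots, npz field container.

VTK files use the legacy ASCII STRUCTURED_POINTS format with all fields
interpolated to cell centres (u, v, p, vorticity, chi), readable by ParaView
and friends.  Force series are plain CSV with header t,tau,Fx,Fy,CL,CD.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "write_force_csv",
    "read_force_csv",
    "write_vtk",
    "write_npz",
    "cell_centred_fields",
]


def write_force_csv(path, records) -> None:
    """Write per-step force records as CSV (t, tau, Fx, Fy, CL, CD)."""
    with open(path, "w") as fh:
        fh.write("t,tau,Fx,Fy,CL,CD\n")
        for r in records:
            fh.write(
                f"{r.t:.12g},{r.tau:.12g},{r.Fx:.12g},{r.Fy:.12g},"
                f"{r.CL:.12g},{r.CD:.12g}\n"
            )


def read_force_csv(path):
    """Read a force CSV back as a pandas DataFrame."""
    import pandas as pd

    return pd.read_csv(path)


def cell_centred_fields(state) -> dict[str, np.ndarray]:
    """Interpolate the staggered state to cell centres (nx, ny arrays)."""
    from .solver import vorticity

    uc = 0.5 * (state.u[:-1, :] + state.u[1:, :])
    vc = 0.5 * (state.v[:, :-1] + state.v[:, 1:])
    w_nodes = vorticity(state)  # (nx-1, ny-1) interior nodes
    w_pad = np.pad(w_nodes, 1, mode="edge")  # (nx+1, ny+1) all nodes approx
    wc = 0.25 * (
        w_pad[:-1, :-1] + w_pad[1:, :-1] + w_pad[:-1, 1:] + w_pad[1:, 1:]
    )
    return {"u": uc, "v": vc, "p": state.p, "vorticity": wc, "chi": state.chi}


def write_vtk(path, state, comment: str = "wingflow snapshot") -> None:
    """Write one flow state as a legacy ASCII VTK structured-points file."""
    fields = cell_centred_fields(state)
    nx, ny = state.p.shape
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write(f"{comment} t={state.t:.9g}\n")
        fh.write("ASCII\n")
        fh.write("DATASET STRUCTURED_POINTS\n")
        fh.write(f"DIMENSIONS {nx} {ny} 1\n")
        fh.write(f"ORIGIN {0.5 * state.dx:.9g} {0.5 * state.dy:.9g} 0\n")
        fh.write(f"SPACING {state.dx:.9g} {state.dy:.9g} 1\n")
        fh.write(f"POINT_DATA {nx * ny}\n")
        for name, arr in fields.items():
            fh.write(f"SCALARS {name} float 1\n")
            fh.write("LOOKUP_TABLE default\n")
            flat = np.asarray(arr).T.ravel()  # x varies fastest
            for k in range(0, len(flat), 6):
                fh.write(" ".join(f"{x:.7g}" for x in flat[k : k + 6]) + "\n")


def write_npz(path, state) -> None:
    """Array-container alternative to VTK (staggered fields as stored)."""
    np.savez(
        path,
        u=state.u,
        v=state.v,
        p=state.p,
        chi=state.chi,
        t=state.t,
        dx=state.dx,
        dy=state.dy,
    )
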