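"""Minimal ASCII VTK XML ImageData (.vti) writer for cell-centred arrays.

Kept dependency-free on purpose: the fields are plain uniform grids and the
ASCII XML flavour of the format is simple enough to emit directly.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np


def write_vti(path, grid, cell_arrays: dict[str, np.ndarray]) -> None:
    """Write cell-centred arrays on a :class:`LabeledGrid` to ``path``.

    Scalar arrays must have the grid's cell shape; vector arrays shape
    ``(3, nx, ny, nz)``.
    """
    nx, ny, nz = grid.shape
    h = grid.spacing
    ox, oy, oz = (float(v) for v in grid.origin)
    lines = [
        '<?xml version="1.0"?>',
        '<VTKFile type="ImageData" version="0.1" byte_order="LittleEndian">',
        f'  <ImageData WholeExtent="0 {nx} 0 {ny} 0 {nz}" '
        f'Origin="{ox} {oy} {oz}" Spacing="{h} {h} {h}">',
        f'    <Piece Extent="0 {nx} 0 {ny} 0 {nz}">',
        "      <CellData>",
    ]
    for name, arr in cell_arrays.items():
        a = np.asarray(arr)
        if a.ndim == 4 and a.shape[0] == 3:
            ncomp = 3
            flat = np.stack(
                [a[i].ravel(order="F") for i in range(3)], axis=-1
            ).ravel()
        else:
            ncomp = 1
            flat = a.ravel(order="F")
        flat = np.nan_to_num(flat, nan=-1.0)
        lines.append(
            f'        <DataArray type="Float64" Name="{name}" '
            f'NumberOfComponents="{ncomp}" format="ascii">'
        )
        lines.append("          " + " ".join(f"{v:.8g}" for v in flat))
        lines.append("        </DataArray>")
    lines += [
        "      </CellData>",
        "    </Piece>",
        "  </ImageData>",
        "</VTKFile>",
    ]
    Path(path).write_text("\n".join(lines) + "\n")
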