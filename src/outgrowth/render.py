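"""Snapshot rendering: label the lattice by cell class and state.

Palette follows the conventional colouring of these simulations:
proliferative normal cells red, senescent cells (either class) blue,
proliferative variant cells green, free surface white.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

PALETTE = {
    "background": (255, 255, 255),
    ("normal", "proliferative"): (220, 50, 47),
    ("variant", "proliferative"): (64, 160, 43),
    ("normal", "senescent"): (38, 80, 210),
    ("variant", "senescent"): (38, 80, 210),
}


def state_to_rgb(state) -> np.ndarray:
    """RGB image (H x W x 3, uint8) of a simulation state."""
    grid = state.grid
    img = np.empty((grid.height, grid.width, 3), dtype=np.uint8)
    img[...] = PALETTE["background"]
    for agent in state.agents.values():
        colour = PALETTE[(agent.cell_class, agent.state)]
        for r, c in agent.footprint.pixels:
            img[r, c] = colour
    return img


def save_png(state, path) -> Path:
    from PIL import Image

    path = Path(path)
    Image.fromarray(state_to_rgb(state)).save(path)
    return path


def save_label_matrix(state, path) -> Path:
    """Plain-text label matrix: 0 free, else the owning agent id."""
    path = Path(path)
    np.savetxt(path, state.grid.occupancy, fmt="%d")
    return path
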