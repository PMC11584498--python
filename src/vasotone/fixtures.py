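"""Programmatic fixtures: coarse meshes and configs for tests and demos."""

from __future__ import annotations

from dataclasses import replace

from .config import Config
from .geometry import Mesh, build_cross_section_mesh


def make_fixture(level: str = "unit") -> tuple[Mesh, Config]:
    """(mesh, config) pair at 'unit' (coarse, fast) or 'integration'
    (production ~1500-element) resolution."""
    cfg = Config()
    if level == "unit":
        solver = replace(cfg.solver, n_radial_media=3, n_radial_adventitia=2,
                         n_circ=24, n_p=5)
        cfg = replace(cfg, solver=solver,
                      network=replace(cfg.network, pre_seconds=1.0))
    elif level == "integration":
        pass  # defaults: 96 x (10 + 5) = 1440 elements
    else:
        raise ValueError("level must be 'unit' or 'integration'")
    mesh = build_cross_section_mesh(
        cfg.geometry, cfg.solver.n_radial_media,
        cfg.solver.n_radial_adventitia, cfg.solver.n_circ, cfg.solver.seed)
    return mesh, cfg
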