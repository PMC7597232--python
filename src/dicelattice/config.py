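"""Run configuration, molecule/table file formats, and run manifests.

Molecule spec files are plain-text key-value::

    component = 1
    faces = 1 0 2 0 0 0      # classes in fixed order +x -x +y -y +z -z

Interaction tables are one ``i j value`` triple per line (classes are
integers, values dimensionless per k_B·T)::

    1 1  0.25
    1 2 -0.25

Run configs are TOML; command-line flags override file values.  Every run
writes a JSON manifest (config + seeds + package version) sufficient to
reproduce it exactly.
"""

from __future__ import annotations

import json
import tomllib
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Any

from .geometry import DIRECTIONS
from .molecules import (
    BUILTIN_NAMES,
    InteractionTable,
    MoleculeSpec,
    builtin_molecule,
)

__all__ = [
    "RunConfig",
    "load_molecule",
    "parse_molecule_text",
    "load_table",
    "parse_table_text",
    "resolve_mixture",
    "write_manifest",
]


def _strip_comment(line: str) -> str:
    return line.split("#", 1)[0].strip()


def parse_molecule_text(text: str) -> MoleculeSpec:
    component = None
    faces = None
    name = ""
    for raw in text.splitlines():
        line = _strip_comment(raw)
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"malformed molecule line: {raw!r}")
        key, value = (part.strip() for part in line.split("=", 1))
        if key == "component":
            component = int(value)
        elif key == "faces":
            faces = tuple(int(tok) for tok in value.split())
        elif key == "name":
            name = value
        else:
            raise ValueError(f"unknown molecule key: {key!r}")
    if component is None or faces is None:
        raise ValueError("molecule file needs both `component` and `faces`")
    if len(faces) != 6:
        raise ValueError(
            f"`faces` needs six classes in order {[repr(d) for d in DIRECTIONS]}"
        )
    return MoleculeSpec(component, faces, name)


def load_molecule(path: str | Path) -> MoleculeSpec:
    return parse_molecule_text(Path(path).read_text())


def parse_table_text(text: str) -> InteractionTable:
    eps: dict[tuple[int, int], float] = {}
    for raw in text.splitlines():
        line = _strip_comment(raw)
        if not line:
            continue
        toks = line.split()
        if len(toks) != 3:
            raise ValueError(f"expected `i j value`, got {raw!r}")
        eps[(int(toks[0]), int(toks[1]))] = float(toks[2])
    if not eps:
        raise ValueError("empty interaction table")
    return InteractionTable(eps)


def load_table(path: str | Path) -> InteractionTable:
    return parse_table_text(Path(path).read_text())


def resolve_mixture(mixture: str) -> tuple[MoleculeSpec, MoleculeSpec]:
    """Parse e.g. ``angled+inert`` into two component specs."""
    parts = [p.strip().lower() for p in mixture.split("+")]
    if len(parts) != 2:
        raise ValueError("mixture must be `<name>+<name>`, e.g. angled+inert")
    for p in parts:
        if p not in BUILTIN_NAMES:
            raise ValueError(f"unknown molecule {p!r}; built-ins: {BUILTIN_NAMES}")
    return builtin_molecule(parts[0], 1), builtin_molecule(parts[1], 2)


@dataclass
class RunConfig:
    """Validated configuration of one CLI run."""

    experiment: str
    mixture: str = "angled+inert"
    component1_file: str | None = None
    component2_file: str | None = None
    table_file: str | None = None
    omega: tuple[float, ...] = (-1.0,)
    x: tuple[float, ...] = (0.5,)
    sphere: bool = False
    seed: int = 0
    restarts: int = 5
    tol: float = 1e-10
    L: int = 10
    equilibration_sweeps: int = 2000
    sampling_sweeps: int = 10000
    rotation_fraction: float = 0.5
    n_betas: int = 12
    output: str = "."

    def __post_init__(self) -> None:
        if not self.omega:
            raise ValueError("omega grid must be non-empty")
        if not self.x:
            raise ValueError("composition grid must be non-empty")
        for x in self.x:
            if not 0.0 <= x <= 1.0:
                raise ValueError(f"molar fraction out of range: {x}")
        if self.L < 2:
            raise ValueError("lattice edge length must be >= 2")
        if self.restarts < 1:
            raise ValueError("at least one solver start is required")

    def components(self) -> tuple[MoleculeSpec, MoleculeSpec]:
        if self.component1_file or self.component2_file:
            if not (self.component1_file and self.component2_file):
                raise ValueError("give both component files or neither")
            return (
                load_molecule(self.component1_file).with_component_id(1),
                load_molecule(self.component2_file).with_component_id(2),
            )
        return resolve_mixture(self.mixture)

    def table(self) -> InteractionTable | None:
        return load_table(self.table_file) if self.table_file else None

    @classmethod
    def from_toml(cls, path: str | Path, **overrides: Any) -> "RunConfig":
        data = tomllib.loads(Path(path).read_text())
        flat: dict[str, Any] = {}
        for key, value in data.items():
            if isinstance(value, dict):
                flat.update(value)
            else:
                flat[key] = value
        for key in ("omega", "x"):
            if key in flat and not isinstance(flat[key], (list, tuple)):
                flat[key] = [flat[key]]
        flat.update({k: v for k, v in overrides.items() if v is not None})
        for key in ("omega", "x"):
            if key in flat:
                flat[key] = tuple(float(v) for v in flat[key])
        return cls(**flat)


def write_manifest(path: str | Path, config: RunConfig | dict,
                   extra: dict | None = None) -> None:
    from . import __version__

    payload = {
        "config": asdict(config) if isinstance(config, RunConfig) else dict(config),
        "package_version": __version__,
    }
    if extra:
        payload.update(extra)
    Path(path).write_text(json.dumps(payload, indent=2, default=str) + "\n")
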