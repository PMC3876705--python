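"""Cell classes and lattice placement for the simulated neocortical patch.

The model distinguishes six cell types: two excitatory pyramidal classes
(superficial ``SPYR`` and deep ``DPYR``) and four inhibitory interneuron
classes (three basket-cell types ``BASK1``-``BASK3`` and chandelier cells
``CHAN``).  Every neuron is a small tree of cylindrical compartments; the
per-class compartment geometries are fixed model constants (see
``COMPARTMENT_TABLE``).

Placement follows the simulators this package emulates: each class lives on
its own regular square lattice covering the whole two-dimensional patch —
5 µm pitch for the pyramidal classes, 15 µm for the interneurons — with an
optional small uniform jitter around each lattice site.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import EmptyNetworkError, InvalidGeometryError

__all__ = [
    "CompartmentRole",
    "CompartmentSpec",
    "CellClass",
    "CLASS_NAMES",
    "PYRAMIDAL_CLASSES",
    "INTERNEURON_CLASSES",
    "build_cell_classes",
    "compartment_area",
    "place_neurons",
    "place_neurons_for_count",
    "patch_side_for_count",
    "write_cell_class_table",
    "read_cell_class_table",
    "write_neuron_table",
    "read_neuron_table",
]


class CompartmentRole(str, Enum):
    """Anatomical role of a cylinder within a neuron."""

    SOMA = "Soma"
    D1 = "D1"
    D2 = "D2"
    D3 = "D3"
    D4 = "D4"
    BD = "BD"  # basal dendrite
    IS = "IS"  # axon initial segment


# Canonical column order used in the tabular interchange format.
_ROLE_ORDER = [
    CompartmentRole.SOMA,
    CompartmentRole.D1,
    CompartmentRole.D2,
    CompartmentRole.D3,
    CompartmentRole.D4,
    CompartmentRole.BD,
    CompartmentRole.IS,
]


@dataclass(frozen=True)
class CompartmentSpec:
    """One cylindrical compartment: role plus diameter and length in µm."""

    role: CompartmentRole
    diameter_um: float
    length_um: float

    def __post_init__(self) -> None:
        if not (self.diameter_um > 0 and self.length_um > 0):
            raise InvalidGeometryError(
                f"compartment {self.role.value}: diameter and length must be "
                f"positive, got ({self.diameter_um}, {self.length_um})"
            )


@dataclass(frozen=True)
class CellClass:
    """A cell type: ordered compartments, synaptic sign and lattice pitch."""

    name: str
    compartments: tuple[CompartmentSpec, ...]
    sign: str  # "excitatory" | "inhibitory"
    grid_spacing_um: float

    def __post_init__(self) -> None:
        if self.sign not in ("excitatory", "inhibitory"):
            raise ValueError(f"unknown sign {self.sign!r}")
        if self.grid_spacing_um <= 0:
            raise InvalidGeometryError("grid spacing must be positive")

    @property
    def n_compartments(self) -> int:
        return len(self.compartments)

    @property
    def roles(self) -> tuple[CompartmentRole, ...]:
        return tuple(c.role for c in self.compartments)


# (diameter µm, length µm) per role; None marks an absent compartment.
COMPARTMENT_TABLE: dict[str, dict[CompartmentRole, tuple[float, float] | None]] = {
    "SPYR": {
        CompartmentRole.SOMA: (16.1, 22.0),
        CompartmentRole.D1: (2.0, 140.0),
        CompartmentRole.D2: (3.3, 190.0),
        CompartmentRole.D3: None,
        CompartmentRole.D4: None,
        CompartmentRole.BD: (2.4, 200.0),
        CompartmentRole.IS: (2.2, 50.0),
    },
    "DPYR": {
        CompartmentRole.SOMA: (16.1, 22.0),
        CompartmentRole.D1: (2.0, 250.0),
        CompartmentRole.D2: (2.9, 400.0),
        CompartmentRole.D3: (4.4, 400.0),
        CompartmentRole.D4: (4.7, 400.0),
        CompartmentRole.BD: (6.3, 200.0),
        CompartmentRole.IS: (2.2, 50.0),
    },
    "BASK1": {
        CompartmentRole.SOMA: (16.1, 22.0),
        CompartmentRole.D1: (2.0, 900.0),
        CompartmentRole.D2: None,
        CompartmentRole.D3: None,
        CompartmentRole.D4: None,
        CompartmentRole.BD: None,
        CompartmentRole.IS: None,
    },
    "BASK2": {
        CompartmentRole.SOMA: (8.0, 11.0),
        CompartmentRole.D1: (2.0, 600.0),
        CompartmentRole.D2: None,
        CompartmentRole.D3: None,
        CompartmentRole.D4: None,
        CompartmentRole.BD: None,
        CompartmentRole.IS: None,
    },
    "BASK3": {
        CompartmentRole.SOMA: (5.4, 5.5),
        CompartmentRole.D1: (2.0, 300.0),
        CompartmentRole.D2: None,
        CompartmentRole.D3: None,
        CompartmentRole.D4: None,
        CompartmentRole.BD: None,
        CompartmentRole.IS: None,
    },
    "CHAN": {
        CompartmentRole.SOMA: (4.0, 5.5),
        CompartmentRole.D1: (2.0, 150.0),
        CompartmentRole.D2: None,
        CompartmentRole.D3: None,
        CompartmentRole.D4: None,
        CompartmentRole.BD: None,
        CompartmentRole.IS: None,
    },
}

CLASS_NAMES = ("SPYR", "DPYR", "BASK1", "BASK2", "BASK3", "CHAN")
PYRAMIDAL_CLASSES = ("SPYR", "DPYR")
INTERNEURON_CLASSES = ("BASK1", "BASK2", "BASK3", "CHAN")

PYRAMIDAL_SPACING_UM = 5.0
INTERNEURON_SPACING_UM = 15.0


def build_cell_classes() -> tuple[CellClass, ...]:
    """Return the six cell classes with their fixed compartment geometry.

    Superficial pyramidal cells have 5 compartments, deep pyramidal cells 7,
    and each interneuron class 2 (soma plus one dendrite).
    """
    classes = []
    for name in CLASS_NAMES:
        row = COMPARTMENT_TABLE[name]
        comps = tuple(
            CompartmentSpec(role, *row[role])
            for role in _ROLE_ORDER
            if row[role] is not None
        )
        excit = name in PYRAMIDAL_CLASSES
        classes.append(
            CellClass(
                name=name,
                compartments=comps,
                sign="excitatory" if excit else "inhibitory",
                grid_spacing_um=(
                    PYRAMIDAL_SPACING_UM if excit else INTERNEURON_SPACING_UM
                ),
            )
        )
    return tuple(classes)


def class_by_name(name: str,
                  classes: Sequence[CellClass] | None = None) -> CellClass:
    for c in classes or build_cell_classes():
        if c.name == name:
            return c
    raise KeyError(name)


def compartment_area(spec: CompartmentSpec) -> float:
    """Lateral membrane area of a cylindrical compartment in µm²."""
    if not (spec.diameter_um > 0 and spec.length_um > 0):
        raise InvalidGeometryError("non-positive compartment dimensions")
    return math.pi * spec.diameter_um * spec.length_um


def _lattice_axis(extent_um: float, spacing_um: float) -> np.ndarray:
    # Sites at multiples of the pitch in [0, extent); the open upper bound
    # keeps a w x w patch from double-counting its far border.
    if extent_um <= 0:
        return np.empty(0)
    return np.arange(0.0, extent_um, spacing_um)


def place_neurons(
    patch_width_um: float,
    patch_height_um: float,
    classes: Sequence[CellClass] | None = None,
    jitter: float = 0.1,
    seed: int = 0,
) -> pd.DataFrame:
    """Place neurons of each class on its lattice over a rectangular patch.

    Parameters
    ----------
    patch_width_um, patch_height_um
        Patch extent; lattice sites occupy ``[0, extent)`` per axis.
    classes
        Cell classes to place (default: all six).  Each class gets an
        independent full lattice at its own pitch; the 5 µm / 15 µm pitch
        ratio yields nine pyramidal sites per interneuron site.
    jitter
        Uniform per-axis displacement amplitude as a fraction of the class
        pitch; 0 reproduces the strictly regular grid.  Jittered positions
        are clipped to the patch.
    seed
        Seed for the displacement draw; placement is deterministic given it.

    Returns
    -------
    pandas.DataFrame
        Columns ``id`` (dense, 0-based, assigned row-major per class in the
        canonical class order), ``cell_class``, ``x_um``, ``y_um``.
    """
    if jitter < 0:
        raise ValueError("jitter must be nonnegative")
    classes = tuple(classes or build_cell_classes())
    rng = np.random.default_rng(seed)
    frames = []
    for cc in classes:
        xs = _lattice_axis(patch_width_um, cc.grid_spacing_um)
        ys = _lattice_axis(patch_height_um, cc.grid_spacing_um)
        if xs.size == 0 or ys.size == 0:
            continue
        gx, gy = np.meshgrid(xs, ys, indexing="xy")
        # row-major: y rows, x fastest
        px = gx.ravel()
        py = gy.ravel()
        if jitter > 0:
            amp = jitter * cc.grid_spacing_um
            px = px + rng.uniform(-amp, amp, px.size)
            py = py + rng.uniform(-amp, amp, py.size)
            px = np.clip(px, 0.0, patch_width_um)
            py = np.clip(py, 0.0, patch_height_um)
        frames.append(
            pd.DataFrame({"cell_class": cc.name, "x_um": px, "y_um": py})
        )
    if not frames:
        raise EmptyNetworkError(
            f"patch {patch_width_um} x {patch_height_um} um holds no lattice site"
        )
    out = pd.concat(frames, ignore_index=True)
    out.insert(0, "id", np.arange(len(out), dtype=np.int64))
    return out


def patch_side_for_count(
    n_neurons: int, classes: Sequence[CellClass] | None = None
) -> float:
    """Side of the smallest square patch whose lattices hold >= n neurons."""
    if n_neurons < 1:
        raise EmptyNetworkError("requested neuron count must be >= 1")
    classes = tuple(classes or build_cell_classes())
    # Site counts only change when the side crosses a multiple of a pitch,
    # so scan sides that are multiples of the finest pitch present.
    pitch = min(c.grid_spacing_um for c in classes)

    def population(side: float) -> int:
        return sum(
            int(np.ceil(side / c.grid_spacing_um)) ** 2 for c in classes
        )

    lo, hi = 1, 2
    while population(hi * pitch) < n_neurons:
        hi *= 2
    while lo < hi:
        mid = (lo + hi) // 2
        if population(mid * pitch) >= n_neurons:
            hi = mid
        else:
            lo = mid + 1
    return lo * pitch


def _apportion(counts: np.ndarray, total: int) -> np.ndarray:
    """Largest-remainder apportionment of `total` across `counts`."""
    counts = np.asarray(counts, dtype=float)
    quota = counts * total / counts.sum()
    base = np.floor(quota).astype(int)
    base = np.minimum(base, counts.astype(int))
    short = total - base.sum()
    order = np.argsort(-(quota - np.floor(quota)), kind="stable")
    for i in order:
        if short == 0:
            break
        if base[i] < counts[i]:
            base[i] += 1
            short -= 1
    return base


def place_neurons_for_count(
    n_neurons: int,
    classes: Sequence[CellClass] | None = None,
    jitter: float = 0.1,
    seed: int = 0,
) -> pd.DataFrame:
    """Place exactly ``n_neurons`` on the smallest square patch that fits.

    The full lattices of the smallest sufficient square patch are generated
    and then truncated to the requested count.  Truncation removes trailing
    (row-major last) sites per class proportionally to class abundance, so
    every class stays represented and the lattice composition is preserved.
    """
    classes = tuple(classes or build_cell_classes())
    side = patch_side_for_count(n_neurons, classes)
    full = place_neurons(side, side, classes, jitter=jitter, seed=seed)
    class_counts = full["cell_class"].value_counts()
    names = [c.name for c in classes if c.name in class_counts.index]
    counts = np.array([class_counts[n] for n in names])
    quotas = _apportion(counts, n_neurons)
    kept = []
    for name, keep in zip(names, quotas):
        sub = full[full["cell_class"] == name]
        kept.append(sub.iloc[: int(keep)])
    out = pd.concat(kept, ignore_index=True)
    out["id"] = np.arange(len(out), dtype=np.int64)
    return out


# ---------------------------------------------------------------------------
# tabular interchange

def write_cell_class_table(classes: Sequence[CellClass], path) -> None:
    """Write the class geometry table as TSV ("diameter,length" per cell)."""
    rows = []
    for cc in classes:
        by_role = {c.role: c for c in cc.compartments}
        row = {"class": cc.name}
        for role in _ROLE_ORDER:
            c = by_role.get(role)
            row[role.value] = (
                f"{c.diameter_um:g},{c.length_um:g}" if c else "—"
            )
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_cell_class_table(path) -> tuple[CellClass, ...]:
    """Inverse of :func:`write_cell_class_table`."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    classes = []
    for _, row in df.iterrows():
        name = row["class"]
        comps = []
        for role in _ROLE_ORDER:
            cell = row[role.value]
            if cell in ("—", "-", "", None) or pd.isna(cell):
                continue
            d, length = (float(v) for v in cell.split(","))
            comps.append(CompartmentSpec(role, d, length))
        excit = name in PYRAMIDAL_CLASSES
        classes.append(
            CellClass(
                name=name,
                compartments=tuple(comps),
                sign="excitatory" if excit else "inhibitory",
                grid_spacing_um=(
                    PYRAMIDAL_SPACING_UM if excit else INTERNEURON_SPACING_UM
                ),
            )
        )
    return tuple(classes)


def write_neuron_table(neurons: pd.DataFrame, path) -> None:
    neurons.to_csv(path, sep="\t", index=False,
                   columns=["id", "cell_class", "x_um", "y_um"])


def read_neuron_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
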