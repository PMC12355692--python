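"""Extended-XYZ dialect for tiered conformer datasets.

Line 1: atom count.  Line 2 (comment): whitespace-separated ``key=value``
pairs; tier energies appear as ``energy_tier0=... energy_tier1=...`` (kJ/mol).
Atom lines: ``element x y z region [fx fy fz per force tier]`` with
coordinates in angstrom, forces in kJ/mol/angstrom and ``region`` an integer
tag (0 = represented-MM set E', 1 = QM set Q, 2 = quantum-core subset of Q).
Which force tiers are present is declared in the comment line as
``force_tiers=0,1``.  Numbers are written with repr-level precision so a
write/read round trip is bit-exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Conformer", "write_xyz", "read_xyz"]

REGION_MM = 0
REGION_QM = 1
REGION_CORE = 2


@dataclass
class Conformer:
    """One structure with optional per-tier energy and force labels."""

    elements: list[str]
    coordinates: np.ndarray  # (n, 3) angstrom
    region: np.ndarray  # (n,) int tags
    energies: dict = field(default_factory=dict)  # tier -> kJ/mol
    forces: dict = field(default_factory=dict)  # tier -> (n, 3) kJ/mol/A

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    @property
    def qm_atoms(self) -> np.ndarray:
        return np.where(self.region >= REGION_QM)[0]

    @property
    def core_atoms(self) -> np.ndarray:
        return np.where(self.region == REGION_CORE)[0]

    def validate(self) -> None:
        if not np.all(np.isfinite(self.coordinates)):
            raise ValueError("non-finite coordinates")
        if self.coordinates.shape != (self.n_atoms, 3):
            raise ValueError("coordinate shape mismatch")
        if self.region.shape != (self.n_atoms,):
            raise ValueError("region tag shape mismatch")


def _fmt(x: float) -> str:
    return format(float(x), ".17g")


def write_xyz(conformers, path) -> None:
    with open(path, "w") as fh:
        for conf in conformers:
            conf.validate()
            tiers = sorted(conf.energies)
            ftiers = sorted(conf.forces)
            fields = [f"energy_tier{t}={_fmt(conf.energies[t])}" for t in tiers]
            if ftiers:
                fields.append("force_tiers=" + ",".join(str(t) for t in ftiers))
            fh.write(f"{conf.n_atoms}\n")
            fh.write(" ".join(fields) + "\n")
            for i in range(conf.n_atoms):
                row = [conf.elements[i]]
                row += [_fmt(v) for v in conf.coordinates[i]]
                row.append(str(int(conf.region[i])))
                for t in ftiers:
                    row += [_fmt(v) for v in conf.forces[t][i]]
                fh.write(" ".join(row) + "\n")


def read_xyz(path) -> list[Conformer]:
    conformers = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    pos = 0
    while pos < len(lines):
        if not lines[pos].strip():
            pos += 1
            continue
        n = int(lines[pos])
        comment = lines[pos + 1]
        energies = {}
        ftiers: list[int] = []
        for token in comment.split():
            key, _, val = token.partition("=")
            if key.startswith("energy_tier"):
                energies[int(key[len("energy_tier"):])] = float(val)
            elif key == "force_tiers":
                ftiers = [int(t) for t in val.split(",") if t]
        elements, coords, region = [], [], []
        forces = {t: [] for t in ftiers}
        for row in lines[pos + 2 : pos + 2 + n]:
            parts = row.split()
            elements.append(parts[0])
            coords.append([float(v) for v in parts[1:4]])
            region.append(int(parts[4]))
            for k, t in enumerate(ftiers):
                forces[t].append([float(v) for v in parts[5 + 3 * k : 8 + 3 * k]])
        conformers.append(
            Conformer(
                elements=elements,
                coordinates=np.array(coords),
                region=np.array(region, dtype=int),
                energies=energies,
                forces={t: np.array(f) for t, f in forces.items()},
            )
        )
        pos += 2 + n
    return conformers
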