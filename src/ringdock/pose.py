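"""Rigid-body pose: unit quaternion + translation, applied as x -> R x + t."""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = ["Pose"]


@dataclasses.dataclass(frozen=True)
class Pose:
    """Rigid transform of a ligand into the receptor frame.

    ``quaternion`` is scalar-last (x, y, z, w) as used by scipy, normalized
    to unit length (checked to 1e-9).
    """

    quaternion: np.ndarray
    translation: np.ndarray
    ligand_id: str = "ligand"
    receptor_id: str = "receptor"

    def __post_init__(self):
        q = np.asarray(self.quaternion, dtype=float)
        t = np.asarray(self.translation, dtype=float)
        if q.shape != (4,) or t.shape != (3,):
            raise ValueError("quaternion must be length 4, translation length 3")
        norm = np.linalg.norm(q)
        if abs(norm - 1.0) > 1e-9:
            if norm == 0:
                raise ValueError("zero quaternion")
            q = q / norm
        object.__setattr__(self, "quaternion", q)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls, **kw) -> "Pose":
        return cls(np.array([0.0, 0.0, 0.0, 1.0]), np.zeros(3), **kw)

    @classmethod
    def from_matrix(cls, rotation: np.ndarray, translation: np.ndarray, **kw) -> "Pose":
        q = Rotation.from_matrix(np.asarray(rotation)).as_quat()
        return cls(q, np.asarray(translation, dtype=float), **kw)

    @property
    def rotation_matrix(self) -> np.ndarray:
        return Rotation.from_quat(self.quaternion).as_matrix()

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords) @ self.rotation_matrix.T + self.translation

    def compose(self, other: "Pose") -> "Pose":
        """self after other: (self o other)(x) = self(other(x))."""
        r1, r2 = self.rotation_matrix, other.rotation_matrix
        return Pose.from_matrix(
            r1 @ r2, r1 @ other.translation + self.translation,
            ligand_id=self.ligand_id, receptor_id=self.receptor_id,
        )

    def to_dict(self) -> dict:
        return {
            "quaternion": self.quaternion.tolist(),
            "translation": self.translation.tolist(),
            "ligand_id": self.ligand_id,
            "receptor_id": self.receptor_id,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Pose":
        return cls(np.asarray(d["quaternion"]), np.asarray(d["translation"]),
                   ligand_id=d.get("ligand_id", "ligand"),
                   receptor_id=d.get("receptor_id", "receptor"))
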