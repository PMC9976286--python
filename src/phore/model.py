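"""Pharmacophore model container and its plain-text serialization.

A model is a named set of typed feature spheres in a common 3D frame plus
exclusion volumes (Xvols) — forbidden spheres representing protein bulk — and
a matching policy.  The on-disk format is a versioned line-oriented text file:

    PHOREMODEL v1 name=<name>
    POLICY min_features_required=all xvol_check=on
    FEATURE NI 1.00000000 0.00000000 0.00000000 1.50000000 [dx dy dz]
    XVOL 4.00000000 2.00000000 0.00000000 1.00000000
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .featperc import FeatureKind, PharmacophoreFeature

__all__ = ["ExclusionVolume", "PharmacophoreModel", "read_model", "write_model"]

FORMAT_VERSION = "v1"


@dataclass(frozen=True)
class ExclusionVolume:
    center: tuple[float, float, float]
    radius: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 < self.radius <= 5.0):
            raise ValueError(f"Xvol radius must be in (0, 5], got {self.radius}")

    @property
    def center_array(self) -> np.ndarray:
        return np.asarray(self.center, dtype=float)


@dataclass
class MatchPolicy:
    min_features_required: int | None = None  # None means "all features mandatory"
    xvol_check: bool = True


@dataclass
class PharmacophoreModel:
    """Named feature arrangement + exclusion volumes + matching policy.

    All features are mandatory unless ``policy.min_features_required`` is
    explicitly lowered; shared-feature models contain only universally
    present features, so mandatory-all is the natural default.
    """

    name: str
    features: list[PharmacophoreFeature]
    xvols: list[ExclusionVolume] = field(default_factory=list)
    policy: MatchPolicy = field(default_factory=MatchPolicy)

    def __post_init__(self) -> None:
        if len(self.features) == 0:
            raise ValueError("a pharmacophore model requires at least one feature")

    @property
    def n_features(self) -> int:
        return len(self.features)

    @property
    def n_xvols(self) -> int:
        return len(self.xvols)

    @property
    def n_required(self) -> int:
        if self.policy.min_features_required is None:
            return len(self.features)
        return min(self.policy.min_features_required, len(self.features))

    def feature_centers(self) -> np.ndarray:
        return np.array([f.center for f in self.features], dtype=float)

    def kind_counts(self) -> dict[FeatureKind, int]:
        out: dict[FeatureKind, int] = {}
        for f in self.features:
            out[f.kind] = out.get(f.kind, 0) + 1
        return out

    def copy(self) -> "PharmacophoreModel":
        return PharmacophoreModel(
            self.name, list(self.features), list(self.xvols),
            MatchPolicy(self.policy.min_features_required, self.policy.xvol_check))

    def __eq__(self, other) -> bool:  # field-for-field, coords to 1e-6
        if not isinstance(other, PharmacophoreModel):
            return NotImplemented
        if (self.name != other.name or self.n_features != other.n_features
                or self.n_xvols != other.n_xvols
                or self.policy.min_features_required != other.policy.min_features_required
                or self.policy.xvol_check != other.policy.xvol_check):
            return False
        for a, b in zip(self.features, other.features):
            if a.kind != b.kind or abs(a.tolerance - b.tolerance) > 1e-6:
                return False
            if np.max(np.abs(np.subtract(a.center, b.center))) > 1e-6:
                return False
            if (a.direction is None) != (b.direction is None):
                return False
            if a.direction is not None and \
                    np.max(np.abs(np.subtract(a.direction, b.direction))) > 1e-6:
                return False
        for a, b in zip(self.xvols, other.xvols):
            if abs(a.radius - b.radius) > 1e-6:
                return False
            if np.max(np.abs(np.subtract(a.center, b.center))) > 1e-6:
                return False
        return True


def write_model(model: PharmacophoreModel, path) -> None:
    if model.n_features == 0:  # defensive; the constructor already blocks this
        raise ValueError("refusing to write a model with no features")
    lines = [f"PHOREMODEL {FORMAT_VERSION} name={model.name}"]
    req = ("all" if model.policy.min_features_required is None
           else str(model.policy.min_features_required))
    xc = "on" if model.policy.xvol_check else "off"
    lines.append(f"POLICY min_features_required={req} xvol_check={xc}")
    for f in model.features:
        parts = [f"FEATURE {f.kind.value}"]
        parts += [f"{c:.8f}" for c in f.center]
        parts.append(f"{f.tolerance:.8f}")
        if f.direction is not None:
            parts += [f"{d:.8f}" for d in f.direction]
        lines.append(" ".join(parts))
    for x in model.xvols:
        lines.append("XVOL " + " ".join(f"{c:.8f}" for c in x.center)
                     + f" {x.radius:.8f}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_model(path) -> PharmacophoreModel:
    with open(path) as fh:
        lines = [ln.strip() for ln in fh if ln.strip()]
    if not lines or not lines[0].startswith("PHOREMODEL "):
        raise ValueError(f"{path}: not a pharmacophore model file")
    header = lines[0].split()
    version = header[1]
    if version != FORMAT_VERSION:
        raise ValueError(
            f"{path}: unsupported model format version {version!r} "
            f"(this reader supports {FORMAT_VERSION})")
    name = lines[0].split("name=", 1)[1] if "name=" in lines[0] else "model"
    policy = MatchPolicy()
    features: list[PharmacophoreFeature] = []
    xvols: list[ExclusionVolume] = []
    for ln in lines[1:]:
        tok = ln.split()
        if tok[0] == "POLICY":
            kv = dict(t.split("=", 1) for t in tok[1:])
            req = kv.get("min_features_required", "all")
            policy.min_features_required = None if req == "all" else int(req)
            policy.xvol_check = kv.get("xvol_check", "on") == "on"
        elif tok[0] == "FEATURE":
            kind = FeatureKind(tok[1])
            vals = [float(v) for v in tok[2:]]
            center, tol = tuple(vals[:3]), vals[3]
            direction = tuple(vals[4:7]) if len(vals) >= 7 else None
            if direction is not None:
                d = np.asarray(direction)
                n = np.linalg.norm(d)
                direction = tuple(d / n) if n > 0 else None
            features.append(PharmacophoreFeature(kind, center, tol, direction))
        elif tok[0] == "XVOL":
            vals = [float(v) for v in tok[1:]]
            xvols.append(ExclusionVolume(tuple(vals[:3]), vals[3]))
        else:
            raise ValueError(f"{path}: unrecognised record {tok[0]!r}")
    return PharmacophoreModel(name, features, xvols, policy)


def transform_model(model: PharmacophoreModel, R: np.ndarray,
                    t: np.ndarray) -> PharmacophoreModel:
    """Rigidly move a model (features and Xvols) to a new frame."""
    from .featperc import transform_features
    feats = transform_features(model.features, R, t)
    xv = [replace(x, center=tuple(np.asarray(x.center) @ np.asarray(R).T + t))
          for x in model.xvols]
    return PharmacophoreModel(model.name, feats, xv,
                              MatchPolicy(model.policy.min_features_required,
                                          model.policy.xvol_check))
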