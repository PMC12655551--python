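"""Synthetic inputs with known ground truth for every pipeline stage.

The generators stand in for the commercial docking stages: ranked
actives-in-decoys score lists at a chosen separability, pose pairs at exact
RMSDs, activity tables drawn from a known linear structure–activity
equation, and ADME property tables with a planted pass count. Every
generator is a pure function of its seed.

Score lists use the binormal model: decoy "goodness" ~ N(0,1), active
goodness ~ N(µ,1) with µ = √2·Φ⁻¹(AUC), so the expected pairwise AUC is
exactly the target (AUC = Φ(µ/√2)). Scores are negated goodness, giving
the lower-is-better orientation of docking energies.

The default activity-table coefficients are the fitted BChE-inhibition
equation pIC50 = 14.588 + 0.197·SHBint2 − 16.205·ETA_Epsilon_5 +
0.181·nAtomP; descriptor ranges are chosen to keep pIC50 in a plausible
3–9 window (descriptor values for the assayed series are unpublished).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import norm

from .adme import PropertyRecord
from .consensus import PosePair
from .exceptions import DataError
from .io import PoseRecord, ScreeningRecord
from .qsar import QsarTable

#: Intercept and coefficients of the default activity-generating equation.
DEFAULT_QSAR_COEFFS = {
    "intercept": 14.588,
    "SHBint2": 0.197,
    "ETA_Epsilon_5": -16.205,
    "nAtomP": 0.181,
}

_HEAVY_ELEMENTS = ("C", "N", "O", "S")


def auc_to_mean_shift(target_auc: float) -> float:
    """µ such that two unit-variance normals µ apart give pairwise AUC =
    Φ(µ/√2) = target."""
    if not (0 < target_auc < 1):
        raise DataError(f"target_auc must be in (0, 1), got {target_auc}")
    return float(np.sqrt(2.0) * norm.ppf(target_auc))


def gen_screening_scores(n_actives: int, n_decoys: int, target_auc: float,
                         seed: int = 0) -> list[ScreeningRecord]:
    """Seeded actives-in-decoys score list, lower-is-better orientation."""
    if n_actives < 1 or n_decoys < 1:
        raise DataError("need at least one active and one decoy")
    mu = auc_to_mean_shift(target_auc)
    rng = np.random.default_rng(seed)
    active_good = rng.normal(mu, 1.0, size=n_actives)
    decoy_good = rng.normal(0.0, 1.0, size=n_decoys)
    width_a = len(str(n_actives))
    width_d = len(str(n_decoys))
    records = [
        ScreeningRecord(f"ACT{i+1:0{width_a}d}", -float(g), "active")
        for i, g in enumerate(active_good)
    ] + [
        ScreeningRecord(f"DEC{i+1:0{width_d}d}", -float(g), "decoy")
        for i, g in enumerate(decoy_good)
    ]
    return records


def gen_pose_pairs(rmsd_values, seed: int = 0, labels=None,
                   n_atoms_range: tuple = (10, 30)) -> list[PosePair]:
    """One pose pair per requested RMSD, exact by construction.

    Pose A is a random heavy-atom cloud; pose B is pose A rigidly
    translated along a random unit vector scaled to the requested RMSD, so
    the in-place RMSD equals the request to machine precision.
    """
    rmsd_values = [float(v) for v in rmsd_values]
    if any(v < 0 for v in rmsd_values):
        raise DataError("requested RMSD values must be non-negative")
    if labels is not None and len(labels) != len(rmsd_values):
        raise DataError("labels length must match rmsd_values length")
    rng = np.random.default_rng(seed)
    lo, hi = n_atoms_range
    pairs = []
    for i, target in enumerate(rmsd_values):
        n_atoms = int(rng.integers(lo, hi + 1))
        elements = tuple(rng.choice(_HEAVY_ELEMENTS, size=n_atoms))
        coords = rng.uniform(-8.0, 8.0, size=(n_atoms, 3))
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        cid = f"POSE{i+1:04d}"
        pose_a = PoseRecord(cid, elements, coords)
        pose_b = pose_a.translated(direction * target)
        label = labels[i] if labels is not None else "unknown"
        pairs.append(PosePair(cid, pose_a, pose_b, label))
    return pairs


def gen_qsar_table(n: int = 15, coefficients: dict = None,
                   noise_sd: float = 0.0, seed: int = 0,
                   n_decoy_descriptors: int = 0) -> QsarTable:
    """Activity table drawn from a known linear equation.

    Descriptor ranges: SHBint2 ~ U(0, 30), ETA_Epsilon_5 ~ U(0.5, 0.9),
    nAtomP ~ integer U(4, 16). Response = equation + N(0, noise_sd).
    ``n_decoy_descriptors`` appends response-independent columns D1..Dk so
    subset selection has something to reject.
    """
    if n < 6:
        raise DataError("need n ≥ 6 compounds")
    if noise_sd < 0:
        raise DataError("noise_sd must be non-negative")
    coeffs = dict(DEFAULT_QSAR_COEFFS if coefficients is None else coefficients)
    intercept = coeffs.pop("intercept")
    rng = np.random.default_rng(seed)
    cols = {}
    for name in coeffs:
        if name == "SHBint2":
            cols[name] = rng.uniform(0.0, 30.0, size=n)
        elif name == "ETA_Epsilon_5":
            cols[name] = rng.uniform(0.5, 0.9, size=n)
        elif name == "nAtomP":
            cols[name] = rng.integers(4, 17, size=n).astype(float)
        else:
            cols[name] = rng.uniform(0.0, 1.0, size=n)
    X = pd.DataFrame(cols)
    y = intercept + sum(coeffs[name] * X[name].to_numpy() for name in coeffs)
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, size=n)
    for k in range(n_decoy_descriptors):
        X[f"D{k+1}"] = rng.uniform(0.0, 10.0, size=n)
    ids = [f"CMP{i+1:03d}" for i in range(n)]
    return QsarTable(ids, X, np.asarray(y, dtype=float))


def _passing_property(rng, cid) -> PropertyRecord:
    return PropertyRecord(
        compound_id=cid,
        mw=float(rng.uniform(200.0, 480.0)),
        logp=float(rng.uniform(0.0, 4.5)),
        hbd=int(rng.integers(0, 5)),
        hba=int(rng.integers(0, 9)),
        psa=float(rng.uniform(40.0, 135.0)),
        logbb=float(rng.uniform(-2.5, 1.0)),
    )


def gen_property_table(n: int, planted_pass: int, seed: int = 0) -> list[PropertyRecord]:
    """Property records of which exactly ``planted_pass`` satisfy the
    drug-likeness filter; the rest each violate ≥ 1 randomly chosen rule."""
    if not (0 <= planted_pass <= n):
        raise DataError(f"planted_pass must be in [0, {n}], got {planted_pass}")
    rng = np.random.default_rng(seed)
    records = []
    for i in range(n):
        cid = f"PROP{i+1:05d}"
        rec = _passing_property(rng, cid)
        if i >= planted_pass:
            # break one or two rules at random
            broken = rng.choice(["ro5", "psa", "logbb"],
                                size=int(rng.integers(1, 3)), replace=False)
            kw = {f: getattr(rec, f) for f in rec.__dataclass_fields__}
            for rule in broken:
                if rule == "ro5":
                    kw["mw"] = float(rng.uniform(520.0, 900.0))
                elif rule == "psa":
                    kw["psa"] = float(rng.uniform(145.0, 250.0))
                else:
                    kw["logbb"] = float(rng.choice([
                        rng.uniform(-6.0, -3.2), rng.uniform(1.4, 3.0)]))
            rec = PropertyRecord(**kw)
        records.append(rec)
    perm = np.random.default_rng(seed + 1).permutation(n)
    return [records[i] for i in perm]


def gen_ic50_table(n: int, n_active: int, seed: int = 0,
                   threshold: float = 100.0) -> list[tuple[str, float]]:
    """Assay outcomes: ``n_active`` compounds below the hit threshold
    (log-uniform 0.1–0.9·threshold), the rest clearly above it."""
    if not (0 <= n_active <= n):
        raise DataError(f"n_active must be in [0, {n}], got {n_active}")
    rng = np.random.default_rng(seed)
    actives = 10 ** rng.uniform(np.log10(0.1), np.log10(0.9 * threshold),
                                size=n_active)
    inactives = 10 ** rng.uniform(np.log10(1.5 * threshold),
                                  np.log10(10 * threshold), size=n - n_active)
    values = np.concatenate([actives, inactives])
    perm = rng.permutation(n)
    return [(f"HIT{i+1:03d}", float(values[j])) for i, j in enumerate(perm)]
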