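"""Synthetic stand-ins for the study inputs, with known ground truth.

The measured inputs of the original study (an LC-MS lipidomic characterisation
of supercritical microalgal extracts, LIPID MAPS candidate structures, and
quantum-chemistry sigma profiles) are emulated here by generators that expose
every planted parameter, so downstream tests assert recovery of known
structure instead of resemblance to unavailable measurements:

* :func:`generate_lipid_library` — ~90 annotated lipids across five classes
  (dominated by glycerophospholipids and glycerolipids), each with 1-6
  candidate isomeric SMILES differing only in double-bond positions — the
  ambiguity mode of shorthand lipid annotation;
* :func:`generate_recovery_surface` — relative abundances over the 12-point
  factorial extraction design from a latent log10 surface with class
  baselines, linear condition effects, non-additive flow x polarity and
  pressure x class terms, lipid random intercepts, Gaussian noise, and
  detection-limit censoring to exact 0.0;
* :func:`generate_sigma_profiles` — Gaussian-mixture sigma profiles whose
  polar-lobe mass tracks lipid class and whose area/volume scale with chain
  length.

All generators are deterministic given ``GeneratorConfig.seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io_core import (
    ExtractionCondition,
    LipidRecord,
    RecoveryTable,
    SigmaProfile,
    ValidationError,
    default_design,
    default_sigma_grid,
)

__all__ = [
    "GeneratorConfig",
    "GroundTruth",
    "generate_lipid_library",
    "generate_recovery_surface",
    "generate_sigma_profiles",
    "generate_planted_family",
    "solvent_sigma_profiles",
]

#: Class composition weights: the extracts are dominated by lipids with a
#: glycerol backbone (glycerophospholipids, glycerolipids), with sphingolipids,
#: prenols and fatty acyls as minor classes.
DEFAULT_CLASS_WEIGHTS = {
    "glycerophospholipids": 0.38,
    "glycerolipids": 0.32,
    "sphingolipids": 0.14,
    "prenols": 0.09,
    "fatty acyls": 0.07,
}

#: Latent log10-abundance baseline per class (relative-abundance scale).
#: Spread across classes mirrors the multi-decade dynamic range of measured
#: lipidomic abundances: major glycerol-backbone classes sit decades above
#: the minor ones.
CLASS_BASELINE = {
    "glycerophospholipids": -1.5,
    "glycerolipids": -2.1,
    "sphingolipids": -3.2,
    "prenols": -4.3,
    "fatty acyls": -2.6,
}

#: Ethanol-flow response per class (per z-unit of flow): polar classes are
#: favoured by more cosolvent, fatty acyls are disfavoured.
CLASS_FLOW_COEF = {
    "glycerophospholipids": 0.25,
    "glycerolipids": 0.30,
    "sphingolipids": 0.10,
    "prenols": 0.05,
    "fatty acyls": -0.20,
}

#: Typical total carbon count per class; the chain-length penalty acts on the
#: deviation from this, so it orders lipids within a class without distorting
#: the class-level composition.
CLASS_CARBON_CENTER = {
    "glycerophospholipids": 36,
    "glycerolipids": 36,
    "sphingolipids": 36,
    "prenols": 15,
    "fatty acyls": 18,
}

#: Mean polarity proxy per class, in [0, 1]; modulates the flow effect.
CLASS_POLARITY = {
    "glycerophospholipids": 0.8,
    "glycerolipids": 0.55,
    "sphingolipids": 0.6,
    "prenols": 0.3,
    "fatty acyls": 0.45,
}


@dataclass(frozen=True)
class GeneratorConfig:
    """All dials of the synthetic-data generator.

    Defaults mirror the study conditions: 89 annotated lipids over the
    bundled 12-condition factorial design, heavy on glycerol-backbone
    classes, with below-detection cells recorded as exact zeros.
    """

    n_lipids: int = 89
    candidates_per_family: tuple[int, int] = (1, 6)
    class_weights: dict = field(default_factory=lambda: dict(DEFAULT_CLASS_WEIGHTS))
    design: list[ExtractionCondition] | None = None
    temp_coef: float = 0.12     # log10 units per 10 degC
    pressure_coef: float = 0.15  # log10 units per 50 bar
    flow_coef_scale: float = 1.0  # multiplies the class flow coefficients
    carbon_coef: float = -0.09  # log10 units per carbon beyond the class center
    db_coef: float = 0.15       # log10 units per double bond
    interactions: bool = True   # flow x polarity and pressure x class terms
    intercept_sd: float = 0.5   # structure-unexplained lipid-to-lipid spread
    noise_sd: float = 0.15      # measurement noise, log10 units
    detection_floor: float = 1e-5  # relative abundance below which cells censor to 0
    seed: int = 0

    def __post_init__(self) -> None:
        w = sum(self.class_weights.values())
        if abs(w - 1.0) > 1e-9:
            raise ValidationError(f"class weights sum to {w}, not 1")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        if self.detection_floor <= 0:
            raise ValidationError("detection_floor must be > 0")
        lo, hi = self.candidates_per_family
        if not (1 <= lo <= hi):
            raise ValidationError("invalid candidates_per_family range")

    def resolved_design(self) -> list[ExtractionCondition]:
        return list(self.design) if self.design is not None else default_design()


@dataclass
class GroundTruth:
    """Planted structure behind one generated recovery surface."""

    latent: np.ndarray          # uncensored log10 abundance, lipid x condition
    deterministic: np.ndarray   # latent minus lipid intercept and noise
    intercepts: np.ndarray      # per-lipid random intercept
    polarity: np.ndarray        # per-lipid polarity proxy in [0, 1]
    coefficients: dict          # planted condition-effect coefficients
    censor_threshold: float     # log10(detection_floor)


# ---------------------------------------------------------------------------
# SMILES construction
# ---------------------------------------------------------------------------


def _acyl_fragment(n_carbons: int, db_start: int, n_db: int) -> str:
    """Hydrocarbon tail of an acyl group written carbonyl-first.

    ``n_carbons`` counts the carbonyl carbon; double bonds are
    methylene-interrupted starting between carbons ``db_start`` and
    ``db_start + 1`` (counting from the carbonyl).
    """
    if n_db and db_start + 3 * (n_db - 1) + 1 > n_carbons:
        raise ValidationError(
            f"cannot place {n_db} double bonds from position {db_start} in C{n_carbons}"
        )
    double_bonds = {db_start + 3 * i for i in range(n_db)}
    out = []
    for c in range(2, n_carbons + 1):
        out.append("=C" if (c - 1) in double_bonds else "C")
    return "".join(out)


def _family_smiles(
    lipid_class: str,
    chain1: int,
    n_db1: int,
    db_starts: list[int],
    chain2: int = 0,
    n_db2: int = 0,
    db2_start: int = 4,
) -> list[str]:
    """Candidate SMILES for one family: same composition, shifted double bonds
    on the first acyl chain (the ambiguity mode of shorthand annotation)."""
    smiles = []
    for s in db_starts:
        if lipid_class == "fatty acyls":
            smiles.append(f"OC(=O){_acyl_fragment(chain1, s, n_db1)}")
        elif lipid_class == "glycerolipids":  # 1,2-diacylglycerol
            r1 = _acyl_fragment(chain1, s, n_db1)
            r2 = _acyl_fragment(chain2, db2_start, n_db2)
            smiles.append(f"OCC(COC(=O){r1})OC(=O){r2}")
        elif lipid_class == "glycerophospholipids":  # phosphatidylcholine
            r1 = _acyl_fragment(chain1, s, n_db1)
            r2 = _acyl_fragment(chain2, db2_start, n_db2)
            smiles.append(f"C[N+](C)(C)CCOP([O-])(=O)OCC(COC(=O){r1})OC(=O){r2}")
        elif lipid_class == "sphingolipids":  # ceramide-like
            r = _acyl_fragment(chain1, s, n_db1)
            smiles.append(f"CCCCCCCCCCCCCC=CC(O)C(CO)NC(=O){r}")
        elif lipid_class == "prenols":
            # isoprenoid of `s` units terminated by a hydroxyl
            smiles.append("CC(C)=CC" + "CC(C)=CC" * (s - 1) + "O")
        else:
            raise ValidationError(f"no template for class {lipid_class!r}")
    return smiles


_CLASS_PREFIX = {
    "fatty acyls": "FA",
    "glycerolipids": "DG",
    "glycerophospholipids": "PC",
    "sphingolipids": "Cer",
    "prenols": "Prenol",
}


def generate_lipid_library(
    config: GeneratorConfig = GeneratorConfig(),
) -> tuple[list[LipidRecord], dict[str, list[str]]]:
    """Generate annotated lipid records plus their candidate structure sets.

    Each family's candidates differ only in double-bond (or isoprene-count)
    position, all SMILES are syntactically valid, and candidates are unique
    within a family.  Returns (records, {shorthand: [smiles, ...]}).
    """
    rng = np.random.default_rng(config.seed)
    classes = list(config.class_weights)
    weights = np.array([config.class_weights[c] for c in classes])
    records: list[LipidRecord] = []
    candidate_sets: dict[str, list[str]] = {}
    lo, hi = config.candidates_per_family
    for i in range(config.n_lipids):
        lipid_class = classes[rng.choice(len(classes), p=weights)]
        n_cand = int(rng.integers(lo, hi + 1))
        if lipid_class == "prenols":
            units = int(rng.integers(2, 6))
            starts = list(range(units, units + n_cand))  # distinct chain lengths
            smiles_list = _family_smiles(lipid_class, 5 * units, units, starts)
            shorthand = f"{_CLASS_PREFIX[lipid_class]}-{units} #{i}"
        else:
            chain1 = int(rng.integers(12, 25))
            n_db1 = int(rng.integers(1, 1 + min(5, (chain1 - 5) // 3)))
            max_start = chain1 - 1 - 3 * (n_db1 - 1)
            possible = list(range(4, max_start + 1))
            if len(possible) < n_cand:
                n_cand = len(possible)
            starts = sorted(rng.choice(possible, size=n_cand, replace=False).tolist())
            if lipid_class == "fatty acyls":
                chain2, n_db2, db2_start = 0, 0, 4
                total_c, total_db = chain1, n_db1
            elif lipid_class == "sphingolipids":
                chain2, n_db2, db2_start = 0, 0, 4
                total_c, total_db = chain1 + 18, n_db1 + 1  # sphingoid base C18:1
            else:
                chain2 = int(rng.integers(12, 25))
                n_db2 = int(rng.integers(0, 1 + min(3, max(0, (chain2 - 5) // 3))))
                max2 = chain2 - 1 - 3 * max(0, n_db2 - 1)
                db2_start = int(rng.integers(4, max(5, max2 + 1))) if n_db2 else 4
                total_c, total_db = chain1 + chain2, n_db1 + n_db2
            smiles_list = _family_smiles(
                lipid_class, chain1, n_db1, starts, chain2, n_db2, db2_start
            )
            shorthand = (
                f"{_CLASS_PREFIX[lipid_class]} {total_c}:{total_db} #{i}"
            )
        lipid_id = f"L{i:03d}"
        records.append(
            LipidRecord(lipid_id=lipid_id, shorthand=shorthand, lipid_class=lipid_class)
        )
        candidate_sets[shorthand] = smiles_list
    return records, candidate_sets


# ---------------------------------------------------------------------------
# Recovery surface over the factorial design
# ---------------------------------------------------------------------------


def _parse_shorthand(shorthand: str) -> tuple[int, int]:
    """(total carbons, total double bonds) from a generated shorthand."""
    head = shorthand.split(" #")[0]
    if head.startswith("Prenol-"):
        units = int(head.split("-")[1])
        return 5 * units, units
    comp = head.split()[-1]
    c, db = comp.split(":")
    return int(c), int(db)


def _condition_z(cond: ExtractionCondition) -> tuple[float, float, float]:
    """Centered/scaled condition coordinates for the latent surface."""
    return (
        (cond.temperature - 50.0) / 10.0,
        (cond.pressure - 200.0) / 50.0,
        (cond.ethanol_flow - 0.75) / 0.15,
    )


def generate_recovery_surface(
    library: list[LipidRecord], config: GeneratorConfig = GeneratorConfig()
) -> tuple[RecoveryTable, GroundTruth]:
    """Simulate relative abundances of a lipid library over the design.

    Latent log10 abundance = class baseline + structure effects (chain-carbon
    count, unsaturation — parsed from the generated shorthand, so recovery is
    largely a function of molecular structure, as descriptors can capture)
    + residual lipid intercept + linear condition effects + (optional)
    non-additive flow x polarity and pressure x class terms + Gaussian noise;
    abundances below ``detection_floor`` are recorded as exact 0.0
    (below-detection censoring).
    """
    rng = np.random.default_rng(config.seed + 1)
    design = config.resolved_design()
    n, m = len(library), len(design)
    intercepts = rng.normal(0.0, config.intercept_sd, size=n)
    polarity = np.clip(
        [rng.normal(CLASS_POLARITY[l.lipid_class], 0.12) for l in library], 0.0, 1.0
    )
    det = np.zeros((n, m))
    for i, lipid in enumerate(library):
        carbons, dbs = _parse_shorthand(lipid.shorthand)
        base = (
            CLASS_BASELINE[lipid.lipid_class]
            + config.carbon_coef * (carbons - CLASS_CARBON_CENTER[lipid.lipid_class])
            + config.db_coef * dbs
        )
        b_flow = CLASS_FLOW_COEF[lipid.lipid_class] * config.flow_coef_scale
        for j, cond in enumerate(design):
            zT, zP, zF = _condition_z(cond)
            y = base + config.temp_coef * zT + config.pressure_coef * zP
            if config.interactions:
                y += b_flow * (0.5 + polarity[i]) * zF
                if lipid.lipid_class == "fatty acyls":
                    y += 0.12 * zP * zF + 0.15 * max(zP, 0.0)
            else:
                y += b_flow * zF
            det[i, j] = y
    latent = det + intercepts[:, None] + rng.normal(0.0, config.noise_sd, size=(n, m))
    abundance = 10.0**latent
    abundance[abundance < config.detection_floor] = 0.0
    table = RecoveryTable(lipids=list(library), conditions=design, abundance=abundance)
    truth = GroundTruth(
        latent=latent,
        deterministic=det,
        intercepts=intercepts,
        polarity=np.asarray(polarity),
        coefficients={
            "temp_coef": config.temp_coef,
            "pressure_coef": config.pressure_coef,
            "carbon_coef": config.carbon_coef,
            "db_coef": config.db_coef,
            "flow_coef": {
                c: CLASS_FLOW_COEF[c] * config.flow_coef_scale for c in CLASS_FLOW_COEF
            },
        },
        censor_threshold=float(np.log10(config.detection_floor)),
    )
    return table, truth


# ---------------------------------------------------------------------------
# Sigma profiles (synthetic; Gaussian mixtures on the standard grid)
# ---------------------------------------------------------------------------

#: Polar-lobe area fraction per class: head-group polarity of the synthetic
#: profiles, largest for phospholipids.
CLASS_POLAR_MASS = {
    "glycerophospholipids": 0.28,
    "glycerolipids": 0.18,
    "sphingolipids": 0.22,
    "prenols": 0.06,
    "fatty acyls": 0.14,
}


def _gaussian_mixture_profile(
    name: str,
    area: float,
    volume: float,
    components: list[tuple[float, float, float]],  # (weight, center, width)
    grid: np.ndarray,
) -> SigmaProfile:
    p = np.zeros_like(grid)
    for w, mu, sd in components:
        p += w * np.exp(-0.5 * ((grid - mu) / sd) ** 2)
    p *= area / p.sum()
    return SigmaProfile(name=name, area=area, volume=volume, grid=grid, p=p)


def generate_sigma_profiles(
    library: list[LipidRecord],
    config: GeneratorConfig = GeneratorConfig(),
    chain_lengths: dict[str, float] | None = None,
) -> dict[str, SigmaProfile]:
    """Synthetic sigma profile per lipid: dominant apolar peak near sigma=0
    plus class-dependent polar side lobes; area/volume grow with chain
    length.  Keyed by lipid_id."""
    rng = np.random.default_rng(config.seed + 2)
    grid = default_sigma_grid()
    profiles: dict[str, SigmaProfile] = {}
    for lipid in library:
        n_c = (
            chain_lengths.get(lipid.lipid_id, 18.0) if chain_lengths else
            float(rng.uniform(16, 40))
        )
        area = 120.0 + 9.5 * n_c + rng.normal(0, 5)
        volume = 90.0 + 12.0 * n_c + rng.normal(0, 5)
        polar = CLASS_POLAR_MASS[lipid.lipid_class] * float(rng.uniform(0.85, 1.15))
        comps = [
            (1.0 - polar, rng.normal(0.0, 0.0008), 0.004),
            (0.55 * polar, -0.013 + rng.normal(0, 0.001), 0.0025),  # HB-donor lobe
            (0.45 * polar, 0.013 + rng.normal(0, 0.001), 0.0025),   # HB-acceptor lobe
        ]
        profiles[lipid.lipid_id] = _gaussian_mixture_profile(
            lipid.lipid_id, area, volume, comps, grid
        )
    return profiles


def solvent_sigma_profiles() -> tuple[SigmaProfile, SigmaProfile]:
    """Synthetic (CO2, ethanol) sigma profiles on the standard grid.

    These are fixed stand-ins with the qualitative shapes of the real
    profiles — CO2: small cavity, quadrupolar twin lobes; ethanol: apolar
    tail peak plus hydroxyl donor/acceptor lobes — not quantum-chemistry
    outputs.
    """
    grid = default_sigma_grid()
    co2 = _gaussian_mixture_profile(
        "CO2-synthetic", 75.0, 62.0,
        [(0.5, -0.006, 0.003), (0.2, 0.0, 0.002), (0.5, 0.006, 0.003)],
        grid,
    )
    ethanol = _gaussian_mixture_profile(
        "ethanol-synthetic", 112.0, 97.0,
        [(0.72, 0.0005, 0.004), (0.16, -0.016, 0.002), (0.12, 0.015, 0.002)],
        grid,
    )
    return co2, ethanol


# ---------------------------------------------------------------------------
# Planted descriptor families (for selector validation)
# ---------------------------------------------------------------------------


def generate_planted_family(
    seed: int,
    n_candidates: int = 5,
    n_descriptors: int = 8,
    noise: float = 0.05,
    spread: float = 1.0,
):
    """A candidate family whose planted member sits at the descriptor-space
    mean of the others (plus ``noise``); used to validate selector recovery.

    Returns (family, planted_candidate_id).  Descriptors are synthetic
    vectors, not computed from the dummy SMILES.
    """
    from .representative import CandidateFamily

    rng = np.random.default_rng(seed)
    others = rng.normal(0.0, spread, size=(n_candidates - 1, n_descriptors))
    planted = others.mean(axis=0) + rng.normal(0.0, noise, size=n_descriptors)
    pos = int(rng.integers(0, n_candidates))
    X = np.insert(others, pos, planted, axis=0)
    ids = [f"cand{i}" for i in range(n_candidates)]
    desc = pd.DataFrame(X, index=ids)
    family = CandidateFamily(
        shorthand=f"planted-{seed}",
        candidates=[(cid, "C") for cid in ids],
        descriptors=desc,
    )
    return family, ids[pos]
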