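"""Self-contained synthetic benchmarks: natives, decoys, contacts, scores.

The generator emulates the raw material of a template-free structure
prediction study: a compact native-like Cβ trace per target, decoy ensembles
obtained by smooth chain-correlated perturbation of the native (so decoys
stay protein-like rather than exploded clouds), noisy predicted contacts of
tunable precision/coverage, and external quality-assessment scores simulated
as noisy monotone functions of true model quality with a per-target offset
(external scores are not comparable between targets, which is precisely what
motivates the classifier).

Two canonical configurations are provided: :func:`informative_spec` (the
default study conditions) and :func:`uninformative_spec` (a negative control
in which every feature channel is decoupled from model correctness).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.PDB import PDBIO
from Bio.PDB.StructureBuilder import StructureBuilder

from . import structure_io
from .featurization import compute_beff
from .quality_scores import tm_score_fixed
from .structure_io import ContactMap, PredictedContactMap, StructureModel

BOND_LENGTH = 3.8  # Cα–Cα virtual bond, Å
MIN_NONBONDED = 3.0  # self-avoidance floor, Å

EXTERNAL_COLUMNS = ("saint2", "proq2d", "proq3d", "proqroscend", "proqrosfad")

_RESIDUES = ("ALA", "LEU", "VAL", "ILE", "PHE", "SER", "THR", "GLU", "LYS", "ASP")


@dataclass(frozen=True)
class BenchmarkSpec:
    """Study conditions of one synthetic benchmark."""

    n_targets: int = 8
    models_per_target: int = 50
    length_range: tuple = (48, 72)
    noise_levels: tuple = (0.5, 1.0, 2.0, 3.0, 4.0, 6.0, 8.0)
    contact_precision: float = 0.7
    contact_coverage: float = 0.7
    informativeness: float = 0.8
    decoy_correlation: float = 0.0
    #: per-target difficulty: multipliers drawn from [1-spread, 1] shrink the
    #: contact precision and score informativeness of hard targets; decoy
    #: noise levels are scaled by a factor from noise_scale_range and offset
    #: by a floor from noise_floor_range, so the hardest targets never
    #: produce a correct model (modelling failures), as in real
    #: template-free sets where roughly 60% of targets succeed.
    difficulty_spread: float = 0.6
    noise_scale_range: tuple = (0.8, 1.6)
    noise_floor_range: tuple = (0.0, 5.0)
    #: fraction of targets whose decoys are all mirror images of the native;
    #: contact maps are chirality-blind, so no feature can see this
    mirror_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_targets < 1 or self.models_per_target < 1:
            raise ValueError("counts must be >= 1")
        if not (0 < self.contact_precision <= 1):
            raise ValueError("contact_precision must be in (0, 1]")
        if not (0 < self.contact_coverage <= 1):
            raise ValueError("contact_coverage must be in (0, 1]")
        if not (0 <= self.informativeness <= 1):
            raise ValueError("informativeness must be in [0, 1]")
        if not (0 <= self.decoy_correlation <= 1):
            raise ValueError("decoy_correlation must be in [0, 1]")
        if not (0 <= self.difficulty_spread < 1):
            raise ValueError("difficulty_spread must be in [0, 1)")


def informative_spec(seed: int = 0, **overrides) -> BenchmarkSpec:
    """The default study conditions: feature channels carry real signal."""
    return replace(BenchmarkSpec(seed=seed), **overrides)


def uninformative_spec(seed: int = 0, **overrides) -> BenchmarkSpec:
    """Negative control: no feature channel is informative about correctness.

    External scores are pure noise (informativeness 0) and predicted contacts
    are unrelated to the native (minimal coverage, low precision).
    Correctness is decided by chirality: decoys carry mild noise (so every
    unmirrored model keeps the fold), but for half the targets every decoy
    is a mirror image of the native, which collapses the TM-score while
    leaving all distance-derived quantities — observed contact maps, their
    alignments, contact satisfaction, and pairwise model similarity —
    exactly unchanged. No feature channel observes the label. More, smaller
    ensembles are used because the control's effective sample size is the
    number of targets.
    """
    base = BenchmarkSpec(seed=seed, n_targets=24, models_per_target=12,
                         informativeness=0.0,
                         contact_precision=0.05, contact_coverage=0.02,
                         noise_levels=(1.0, 1.5, 2.0), mirror_fraction=0.5,
                         difficulty_spread=0.0, noise_scale_range=(1.0, 1.0),
                         noise_floor_range=(0.0, 0.0))
    return replace(base, **overrides)


@dataclass
class TargetBundle:
    """Everything the pipeline needs for one synthetic target."""

    target_id: str
    native: StructureModel
    models: list
    tms: np.ndarray
    predicted: PredictedContactMap
    msa: list
    external: pd.DataFrame  # per-model simulated external scores


@dataclass
class Benchmark:
    spec: BenchmarkSpec
    targets: list = field(default_factory=list)


def _random_walk(length: int, rng: np.random.Generator) -> np.ndarray:
    """Persistent random walk with 3.8 Å steps."""
    coords = np.zeros((length, 3))
    direction = rng.standard_normal(3)
    direction /= np.linalg.norm(direction)
    for i in range(1, length):
        step = 0.7 * direction + rng.standard_normal(3)
        step /= np.linalg.norm(step)
        coords[i] = coords[i - 1] + BOND_LENGTH * step
        direction = step
    return coords


def _relax(coords: np.ndarray, rng: np.random.Generator,
           n_iter: int = 400) -> np.ndarray:
    """Collapse the walk into a compact, self-avoiding globule."""
    L = len(coords)
    target_rg = 2.45 * L ** 0.37
    idx = np.arange(L)
    sep = np.abs(idx[:, None] - idx[None, :])
    for _ in range(n_iter):
        # bond restraint
        bond = coords[1:] - coords[:-1]
        bl = np.linalg.norm(bond, axis=1, keepdims=True)
        corr = 0.5 * (bl - BOND_LENGTH) / bl * bond
        coords[:-1] += corr
        coords[1:] -= corr
        # excluded volume for |i-j| >= 2
        diff = coords[:, None, :] - coords[None, :, :]
        dist = np.linalg.norm(diff, axis=-1)
        np.fill_diagonal(dist, 1e9)
        close = (dist < 4.2) & (sep >= 2)
        if close.any():
            factor = np.where(close, (4.2 - dist) / dist, 0.0)
            coords += 0.25 * (factor[..., None] * diff).sum(axis=1)
        # compaction toward target radius of gyration
        centroid = coords.mean(axis=0)
        rg = math.sqrt(np.mean(np.sum((coords - centroid) ** 2, axis=1)))
        if rg > target_rg:
            coords += 0.02 * (centroid - coords)
    return coords


def synth_native(length: int, seed: int, min_separation: int = 5,
                 density_band: tuple = (1.0, 3.0),
                 max_attempts: int = 25) -> StructureModel:
    """Compact self-avoiding native-like trace with realistic contact density.

    Retries from fresh random walks until the 8 Å contact density (contacts
    per residue at the given separation filter) lands inside ``density_band``
    and no non-bonded pair is closer than 3 Å.
    """
    if length < 16:
        raise ValueError("length must be >= 16")
    rng = np.random.default_rng(np.random.SeedSequence([seed, length]))
    names_rng = np.random.default_rng(np.random.SeedSequence([seed, length, 7]))
    names = tuple(
        "GLY" if names_rng.random() < 0.08 else _RESIDUES[names_rng.integers(len(_RESIDUES))]
        for _ in range(length)
    )
    for _ in range(max_attempts):
        coords = _relax(_random_walk(length, rng), rng)
        d = np.linalg.norm(coords[:, None] - coords[None, :], axis=-1)
        iu = np.triu_indices(length, 2)
        if d[iu].min() < MIN_NONBONDED:
            continue
        su = np.triu_indices(length, min_separation)
        density = (d[su] < 8.0).sum() / length
        if density_band[0] <= density <= density_band[1]:
            return StructureModel(
                model_id="native", target_id=f"T{seed:04d}",
                indices=np.arange(1, length + 1), names=names, coords=coords)
    raise RuntimeError(
        f"could not generate a native of length {length} within constraints")


def _smooth_field(length: int, rng: np.random.Generator,
                  n_modes: int = 4) -> np.ndarray:
    """Unit-RMS chain-correlated displacement field (low-frequency modes)."""
    t = np.arange(length) / length
    field = np.zeros((length, 3))
    for _ in range(n_modes):
        freq = rng.uniform(0.5, 2.5)
        phase = rng.uniform(0, 2 * np.pi, size=3)
        amp = rng.standard_normal(3)
        field += amp * np.sin(2 * np.pi * freq * t[:, None] + phase)
    field += 0.15 * rng.standard_normal((length, 3))
    rms = math.sqrt(np.mean(np.sum(field ** 2, axis=1)))
    return field / rms


def _random_rigid(coords: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    from scipy.spatial.transform import Rotation
    R = Rotation.random(random_state=np.random.RandomState(rng.integers(2**31))).as_matrix()
    t = rng.uniform(-20, 20, size=3)
    return coords @ R.T + t


def synth_decoys(native: StructureModel, noise_levels, n_per_level: int,
                 seed: int, correlation: float = 0.0,
                 mirror: bool = False):
    """Decoy ensemble spanning a quality range, with true TM labels.

    Each decoy displaces the native by a smooth chain-correlated field of the
    given RMS magnitude plus a random rigid motion; larger noise gives
    stochastically lower TM. ``correlation`` mixes in a displacement field
    shared by all decoys of the target. ``mirror`` reflects every decoy
    (wrong-handed fold: distances and contact maps are unchanged, TM-score
    collapses).
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 11]))
    L = native.length
    shared = _smooth_field(L, rng)
    models, tms = [], []
    idx = 0
    for level in noise_levels:
        for _ in range(n_per_level):
            own = _smooth_field(L, rng)
            disp = (math.sqrt(correlation) * shared
                    + math.sqrt(1.0 - correlation) * own) * level
            perturbed = native.coords + disp
            if mirror:
                centre = perturbed.mean(axis=0)
                perturbed = perturbed.copy()
                perturbed[:, 2] = 2 * centre[2] - perturbed[:, 2]
            coords = _random_rigid(perturbed, rng)
            decoy = StructureModel(
                model_id=f"{native.target_id}_m{idx:03d}",
                target_id=native.target_id,
                indices=native.indices.copy(), names=native.names,
                coords=coords)
            models.append(decoy)
            exact_copy = level == 0 and not mirror
            tms.append(1.0 if exact_copy else tm_score_fixed(decoy, native))
            idx += 1
    return models, np.array(tms)


def synth_predicted_contacts(native_map: ContactMap, precision: float,
                             coverage: float, seed: int) -> PredictedContactMap:
    """Noisy predicted contacts with tunable precision and coverage.

    Keeps a ``coverage`` fraction of native contacts as true positives and
    adds wrong pairs so that the PPV against the native equals ``precision``;
    true entries draw higher probabilities than false ones (all above the
    0.5 working threshold).
    """
    if not (0 < precision <= 1) or not (0 < coverage <= 1):
        raise ValueError("precision and coverage must be in (0, 1]")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 13]))
    native = sorted(native_map.contacts)
    n_tp = max(int(round(coverage * len(native))), 1)
    keep = rng.choice(len(native), size=n_tp, replace=False)
    true_pairs = [native[i] for i in sorted(keep)]
    n_fp = int(round(n_tp * (1.0 - precision) / precision))
    L, ms = native_map.length, native_map.min_separation
    candidates = [(i, j) for i in range(1, L + 1) for j in range(i + ms, L + 1)
                  if (i, j) not in native_map.contacts]
    if n_fp > len(candidates):
        raise ValueError("requested precision/coverage impossible for this map")
    pick = rng.choice(len(candidates), size=n_fp, replace=False)
    false_pairs = [candidates[i] for i in sorted(pick)]
    entries = [(i, j, float(rng.uniform(0.60, 0.95))) for i, j in true_pairs]
    entries += [(i, j, float(rng.uniform(0.51, 0.75))) for i, j in false_pairs]
    return PredictedContactMap(length=L, entries=tuple(sorted(entries)))


def synth_external_scores(tms, informativeness: float, seed: int,
                          columns=EXTERNAL_COLUMNS,
                          target_offset_sd: float = 1.0) -> pd.DataFrame:
    """External QA scores as informativeness-weighted mixes of quality and noise.

    Each column is a * z(TM) + sqrt(1 - a^2) * noise + per-target offset with
    a = informativeness, so `a` is the within-target correlation with true
    quality. The offset makes raw scores incomparable between targets.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 17]))
    tms = np.asarray(tms, dtype=float)
    sd = tms.std()
    z = (tms - tms.mean()) / sd if sd > 0 else np.zeros_like(tms)
    a = informativeness
    data = {}
    for col in columns:
        offset = rng.normal(0.0, target_offset_sd)
        noise = rng.standard_normal(len(tms))
        data[col] = a * z + math.sqrt(max(1.0 - a * a, 0.0)) * noise + offset
    return pd.DataFrame(data)


def synth_msa(length: int, seed: int, n_sequences: int = 24) -> list:
    """Small gapless synthetic alignment with a few redundancy clusters."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 19]))
    alphabet = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
    ref = alphabet[rng.integers(len(alphabet), size=length)]
    seqs = ["".join(ref)]
    while len(seqs) < n_sequences:
        rate = 0.05 if rng.random() < 0.5 else 0.45
        mut = ref.copy()
        mask = rng.random(length) < rate
        mut[mask] = alphabet[rng.integers(len(alphabet), size=int(mask.sum()))]
        seqs.append("".join(mut))
    return seqs


def generate_benchmark(spec: BenchmarkSpec) -> Benchmark:
    """Build an in-memory benchmark: one bundle per target."""
    bench = Benchmark(spec=spec)
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 23]))
    n_levels = len(spec.noise_levels)
    base = spec.models_per_target // n_levels
    extra = spec.models_per_target - base * n_levels
    per_level = [base + (1 if k < extra else 0) for k in range(n_levels)]
    for t in range(spec.n_targets):
        tseed = int(spec.seed * 10000 + t)
        length = int(rng.integers(spec.length_range[0], spec.length_range[1] + 1))
        native = synth_native(length, seed=tseed)
        target_id = f"T{tseed:05d}"
        native.target_id = target_id
        # target difficulty: hard targets get noisier decoys, worse contacts
        # and less informative external scores, mirroring the Beff gradient
        # of real template-free sets
        ease = 1.0 - spec.difficulty_spread * rng.random()
        noise_scale = rng.uniform(*spec.noise_scale_range)
        noise_floor = rng.uniform(*spec.noise_floor_range)
        mirrored = bool(rng.random() < spec.mirror_fraction)
        models, tms = [], []
        for level, n in zip(spec.noise_levels, per_level):
            if n == 0:
                continue
            m, l_tms = synth_decoys(native, [level * noise_scale + noise_floor], n,
                                    seed=tseed * 31 + int(level * 100),
                                    correlation=spec.decoy_correlation,
                                    mirror=mirrored)
            models.extend(m)
            tms.append(l_tms)
        tms = np.concatenate(tms)
        for k, m in enumerate(models):
            m.model_id = f"{target_id}_m{k:03d}"
        native_map = structure_io.observed_contact_map(native)
        predicted = synth_predicted_contacts(
            native_map, max(spec.contact_precision * ease, 0.02),
            spec.contact_coverage, seed=tseed)
        external = synth_external_scores(tms, spec.informativeness * ease,
                                         seed=tseed)
        external.insert(0, "model_id", [m.model_id for m in models])
        external.insert(0, "target_id", target_id)
        msa = synth_msa(length, seed=tseed)
        bench.targets.append(TargetBundle(
            target_id=target_id, native=native, models=models, tms=tms,
            predicted=predicted, msa=msa, external=external))
    return bench


def write_model(model: StructureModel, path) -> None:
    """Write the reduced representation as a single-chain PDB file.

    One representative atom per residue: CB, or CA for glycine.
    """
    builder = StructureBuilder()
    builder.init_structure(model.model_id)
    builder.init_model(0)
    builder.init_chain("A")
    builder.init_seg("    ")
    for serial, (idx, name, coord) in enumerate(model.residues, start=1):
        builder.init_residue(name, " ", int(idx), " ")
        atom = "CA" if name == "GLY" else "CB"
        builder.init_atom(atom, np.asarray(coord, dtype=float), 0.0, 1.0,
                          " ", atom.ljust(3), serial, element="C")
    io = PDBIO()
    io.set_structure(builder.get_structure())
    io.save(str(path))


def make_benchmark(spec: BenchmarkSpec, out_dir) -> Benchmark:
    """Materialise a benchmark on disk (PDB decoys, RR files, TSV tables)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bench = generate_benchmark(spec)
    (out / "natives").mkdir(exist_ok=True)
    labels = []
    externals = []
    for bundle in bench.targets:
        tdir = out / bundle.target_id
        tdir.mkdir(exist_ok=True)
        write_model(bundle.native, out / "natives" / f"{bundle.target_id}.pdb")
        for m in bundle.models:
            write_model(m, tdir / f"{m.model_id}.pdb")
        structure_io.write_contacts(out / f"{bundle.target_id}.rr", bundle.predicted)
        with open(out / f"{bundle.target_id}.fasta", "w") as fh:
            for k, seq in enumerate(bundle.msa):
                fh.write(f">seq{k}\n{seq}\n")
        labels.append(pd.DataFrame({
            "target_id": bundle.target_id,
            "model_id": [m.model_id for m in bundle.models],
            "tm": np.round(bundle.tms, 6),
        }))
        externals.append(bundle.external.round(6))
    structure_io.write_score_table(pd.concat(labels, ignore_index=True),
                                   out / "labels.tsv")
    structure_io.write_score_table(pd.concat(externals, ignore_index=True),
                                   out / "scores.tsv")
    return bench
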