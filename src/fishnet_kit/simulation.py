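"""Ground-truth-bearing synthetic datasets for benchmarking complex selection.

The generator emulates a two-class spectral-count screen:

* a base count matrix (per-protein log-normal abundance, Poisson sampling
  noise per sample) when no real matrix is supplied;
* multiplicative spike-in of a chosen fraction of proteins (default 20%)
  with effect sizes p drawn from {0.2, 0.5, 0.8, 1.0, 2.0}, applied as
  count' = count * (1 + p) in exactly one class;
* pseudo-class construction: an even set of same-condition samples is split
  randomly in half and one half is spiked, giving a dataset whose only class
  signal is the spike;
* pseudo-complexes: truth proteins are ordered by Ward-linkage hierarchical
  clustering on Euclidean distances (so co-expressed proteins are adjacent),
  split into contiguous near-equal chunks, and optionally diluted to a target
  purity by swapping members for unused non-differential proteins; an equal
  number of non-differential pseudo-complexes is built the same way.

All randomness flows through ``numpy.random.default_rng`` seeded from the
spec, so a fixed seed reproduces the dataset bit for bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage

from .data_io import ComplexSet, ValidationError


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


@dataclass(frozen=True)
class SimulationSpec:
    """Spike-in parameters: differential fraction, effect sizes, seed."""

    diff_fraction: float = 0.20
    effect_sizes: tuple[float, ...] = (0.2, 0.5, 0.8, 1.0, 2.0)
    n_replicate_datasets: int = 100
    seed: int | None = None

    def __post_init__(self) -> None:
        if not (0 < self.diff_fraction < 1):
            raise ValidationError("diff_fraction must be in (0, 1)")
        if not self.effect_sizes or any(e <= 0 for e in self.effect_sizes):
            raise ValidationError("effect sizes must be positive")


@dataclass
class SimulatedDataset:
    """A spiked matrix with its labels and per-protein ground truth."""

    matrix: pd.DataFrame
    classes: pd.Series
    truth_proteins: set[str]
    effects: dict[str, float]
    spiked_class: str


@dataclass(frozen=True)
class PseudoComplexSpec:
    """Pseudo-complex construction: how many differential complexes, purity."""

    n_diff_complexes: int
    purity: float = 1.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_diff_complexes < 1:
            raise ValidationError("n_diff_complexes must be >= 1")
        if not (0 < self.purity <= 1):
            raise ValidationError("purity must be in (0, 1]")


def synthesize_base_matrix(
    n_proteins: int = 1000,
    n_samples: int = 12,
    seed: int | None = None,
    log_mean: float = 2.0,
    log_sd: float = 1.0,
    dispersion: float = 0.0,
) -> pd.DataFrame:
    """Spectral-count-like base matrix: lognormal protein means, Poisson noise.

    The defaults give a median expected count around exp(2) ~ 7 with a long
    right tail and naturally occurring zeros for low-abundance proteins,
    which is the regime the rank-weight schemes are designed for.

    ``dispersion`` adds per-cell multiplicative lognormal noise (sigma on the
    log scale) on top of the Poisson sampling, emulating the technical
    overdispersion of real spectral counts; it destabilises abundance ranks
    between samples, which is what makes a dataset "noisy" for the
    rank-weight schemes.  0 keeps pure Poisson counts.
    """
    rng = np.random.default_rng(seed)
    lam = rng.lognormal(mean=log_mean, sigma=log_sd, size=n_proteins)
    cell_rates = np.tile(lam[:, None], (1, n_samples))
    if dispersion > 0:
        cell_rates = cell_rates * rng.lognormal(0.0, dispersion, size=cell_rates.shape)
    counts = rng.poisson(cell_rates).astype(float)
    width = len(str(n_proteins))
    proteins = [f"P{i + 1:0{width}d}" for i in range(n_proteins)]
    samples = [f"S{j + 1:02d}" for j in range(n_samples)]
    matrix = pd.DataFrame(counts, index=proteins, columns=samples)
    # a sample with no positive count cannot be ranked; resample such columns
    for j in range(n_samples):
        while not (matrix.iloc[:, j] > 0).any():  # pragma: no cover - vanishingly rare
            matrix.iloc[:, j] = rng.poisson(lam).astype(float)
    return matrix


def _spike(
    base: pd.DataFrame,
    classes: pd.Series,
    rng: np.random.Generator,
    diff_fraction: float,
    effect_sizes: tuple[float, ...],
    which_class: str,
) -> SimulatedDataset:
    n_prot = base.shape[0]
    k = _round_half_up(diff_fraction * n_prot)
    if k < 1:
        raise ValidationError("diff_fraction times protein count is below 1")
    chosen_idx = rng.choice(n_prot, size=k, replace=False)
    chosen = [str(base.index[i]) for i in sorted(chosen_idx)]
    effects = {g: float(rng.choice(np.asarray(effect_sizes, dtype=float))) for g in chosen}
    matrix = base.copy()
    target_cols = [s for s in matrix.columns if classes[s] == which_class]
    for g in chosen:
        matrix.loc[g, target_cols] = matrix.loc[g, target_cols] * (1.0 + effects[g])
    return SimulatedDataset(
        matrix=matrix,
        classes=classes.copy(),
        truth_proteins=set(chosen),
        effects=effects,
        spiked_class=which_class,
    )


def spike_in(
    base: pd.DataFrame,
    classes: pd.Series,
    spec: SimulationSpec,
    which_class: str,
) -> SimulatedDataset:
    """Multiply a random differential fraction of proteins by (1 + p) in one class."""
    if base.shape[0] == 0:
        raise ValidationError("base matrix is empty")
    labels = sorted(pd.Series(classes).unique())
    if which_class not in labels:
        raise ValidationError(f"which_class={which_class!r} is not one of {labels}")
    rng = np.random.default_rng(spec.seed)
    return _spike(base, classes, rng, spec.diff_fraction, spec.effect_sizes, which_class)


def make_pseudo_class_dataset(
    controls: pd.DataFrame,
    spec: SimulationSpec,
    class_labels: tuple[str, str] = ("control", "test"),
) -> SimulatedDataset:
    """Split same-condition samples into two random halves and spike one half."""
    n = controls.shape[1]
    if n < 4 or n % 2 != 0:
        raise ValidationError("pseudo-class construction needs an even sample count >= 4")
    rng = np.random.default_rng(spec.seed)
    perm = rng.permutation(n)
    labels = np.empty(n, dtype=object)
    labels[perm[: n // 2]] = class_labels[0]
    labels[perm[n // 2 :]] = class_labels[1]
    classes = pd.Series(labels, index=controls.columns, name="class")
    return _spike(controls, classes, rng, spec.diff_fraction, spec.effect_sizes, class_labels[1])


def _cluster_order(matrix: pd.DataFrame, proteins: list[str]) -> list[str]:
    """Order proteins by Ward-linkage leaf order on Euclidean distances."""
    if len(proteins) < 3:
        return list(proteins)
    X = matrix.loc[proteins].to_numpy(dtype=float)
    Z = linkage(X, method="ward")
    return [proteins[i] for i in leaves_list(Z)]


def build_pseudo_complexes(
    dataset: SimulatedDataset, spec: PseudoComplexSpec
) -> ComplexSet:
    """Chunk clustered truth proteins into complexes; dilute to target purity.

    Returns differential and non-differential pseudo-complexes with truth
    labels.  Replacement proteins for purity dilution come from
    non-differential proteins not used in the non-differential complexes,
    so truth never leaks between the two groups.
    """
    rng = np.random.default_rng(spec.seed)
    truth = sorted(dataset.truth_proteins)
    if len(truth) < 3 * spec.n_diff_complexes:
        raise ValidationError(
            f"{len(truth)} truth proteins cannot fill {spec.n_diff_complexes} complexes of size >= 3"
        )
    pool = sorted(set(map(str, dataset.matrix.index)) - dataset.truth_proteins)
    if len(pool) < len(truth):
        raise ValidationError("not enough non-differential proteins to mirror the truth set")

    ordered_truth = _cluster_order(dataset.matrix, truth)
    diff_chunks = [list(chunk) for chunk in np.array_split(np.asarray(ordered_truth, dtype=object), spec.n_diff_complexes)]

    sampled_idx = rng.choice(len(pool), size=len(truth), replace=False)
    sampled = [pool[i] for i in sorted(sampled_idx)]
    ordered_nondiff = _cluster_order(dataset.matrix, sampled)
    nondiff_chunks = [list(chunk) for chunk in np.array_split(np.asarray(ordered_nondiff, dtype=object), spec.n_diff_complexes)]

    spare = [p for p in pool if p not in set(sampled)]
    spare = [spare[i] for i in rng.permutation(len(spare))]
    next_spare = 0
    if spec.purity < 1.0:
        for chunk in diff_chunks:
            size = len(chunk)
            n_keep = _round_half_up(spec.purity * size)
            n_replace = size - n_keep
            if n_replace == 0:
                continue
            if next_spare + n_replace > len(spare):
                raise ValidationError("not enough unused non-differential proteins for purity dilution")
            positions = sorted(rng.choice(size, size=n_replace, replace=False))
            for pos in positions:
                chunk[pos] = spare[next_spare]
                next_spare += 1

    width = len(str(spec.n_diff_complexes))
    complexes: dict[str, list[str]] = {}
    truth_labels: dict[str, bool] = {}
    for k, chunk in enumerate(diff_chunks):
        cid = f"diff_{k + 1:0{width}d}"
        complexes[cid] = list(chunk)
        truth_labels[cid] = True
    for k, chunk in enumerate(nondiff_chunks):
        cid = f"nondiff_{k + 1:0{width}d}"
        complexes[cid] = list(chunk)
        truth_labels[cid] = False
    descriptions = {cid: ("differential" if truth_labels[cid] else "non_differential") for cid in complexes}
    return ComplexSet(complexes=complexes, descriptions=descriptions, truth=truth_labels)


def shuffle_labels(classes: pd.Series, seed: int | None = None) -> pd.Series:
    """Permute the label multiset over samples (class sizes preserved)."""
    rng = np.random.default_rng(seed)
    values = classes.to_numpy(copy=True)
    return pd.Series(values[rng.permutation(len(values))], index=classes.index, name=classes.name)


def simulate_dataset(
    n_proteins: int = 1000,
    samples_per_class: int = 6,
    spec: SimulationSpec | None = None,
    n_complexes: int = 62,
    purity: float = 1.0,
    seed: int | None = None,
    class_labels: tuple[str, str] = ("control", "test"),
    dispersion: float = 0.0,
) -> tuple[SimulatedDataset, ComplexSet]:
    """One-call study dataset: base matrix, spike-in, pseudo-complexes.

    ``seed`` drives three independent streams (base counts, spike, complex
    construction); a spec seed, if given, overrides the spike stream.
    ``dispersion`` is passed to the base-count generator.
    """
    ss = np.random.SeedSequence(seed)
    s_base, s_spike, s_cplx = (int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(3))
    spec = spec or SimulationSpec(seed=s_spike)
    if spec.seed is None:
        spec = SimulationSpec(
            diff_fraction=spec.diff_fraction, effect_sizes=spec.effect_sizes,
            n_replicate_datasets=spec.n_replicate_datasets, seed=s_spike,
        )
    base = synthesize_base_matrix(n_proteins, 2 * samples_per_class, seed=s_base, dispersion=dispersion)
    classes = pd.Series(
        [class_labels[0]] * samples_per_class + [class_labels[1]] * samples_per_class,
        index=base.columns, name="class",
    )
    dataset = spike_in(base, classes, spec, which_class=class_labels[1])
    complexes = build_pseudo_complexes(
        dataset, PseudoComplexSpec(n_diff_complexes=n_complexes, purity=purity, seed=s_cplx)
    )
    return dataset, complexes
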