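"""Study-scale experiment recipes built from the library primitives.

These functions run the standard evaluation designs end to end — null
calibration, F-score benchmarking over replicate spiked datasets, the
fuzzification stability contrast, the real-vs-shuffled cross-validation
contrast and the pseudo-class false-positive evaluation — at sizes that
finish in minutes on one CPU.  They are what the acceptance script and the
top-level tests execute; every random draw is derived from a single seed.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .benchmarks import (
    cross_validate,
    false_positive_eval,
    mean_pairwise_jaccard,
    precision_recall_f,
    stability_resampling,
)
from .data_io import ComplexSet
from .registry import resolve_method
from .simulation import SimulationSpec, simulate_dataset, synthesize_base_matrix

DIRECTIONAL_METHODS = ("snet", "fsnet", "pfsnet", "ffishnet", "fishnet")


def _child_seeds(seed: int | None, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(n)]


def random_complexes(
    proteins: Sequence[str],
    n_complexes: int = 60,
    size_range: tuple[int, int] = (3, 20),
    seed: int | None = None,
) -> ComplexSet:
    """Random protein groups with a filtered-CORUM-like size mix (3-20)."""
    rng = np.random.default_rng(seed)
    proteins = list(proteins)
    sizes = rng.integers(size_range[0], size_range[1] + 1, size=n_complexes)
    width = len(str(n_complexes))
    return ComplexSet(
        {
            f"C{k + 1:0{width}d}": [proteins[i] for i in rng.choice(len(proteins), s, replace=False)]
            for k, s in enumerate(sizes)
        }
    )


def null_calibration(
    methods: Sequence[str] = ("qpsp", "fsnet", "pfsnet", "gsea", "ffishnet"),
    n_rounds: int = 500,
    n_proteins: int = 1000,
    samples_per_class: int = 6,
    n_complexes: int = 60,
    alpha: float = 0.05,
    seed: int | None = None,
) -> pd.DataFrame:
    """Selection rates under a no-effect simulation, one row per method.

    Each round draws a fresh base matrix (no spiked effects) with an
    arbitrary balanced two-class labelling and a fresh random complex set, so
    rounds are fully independent replicates of the design and the
    across-round Monte-Carlo standard error covers every variance source.
    For directional methods the rate counts each one-sided test separately
    (per-direction rate).
    """
    seed_cplx, seed_rounds = _child_seeds(seed, 2)
    round_seeds = _child_seeds(seed_rounds, n_rounds)
    cplx_seeds = _child_seeds(seed_cplx, n_rounds)
    labels = ["a"] * samples_per_class + ["b"] * samples_per_class
    per_round: dict[str, list[float]] = {m: [] for m in methods}
    for rs, cxs in zip(round_seeds, cplx_seeds):
        matrix = synthesize_base_matrix(n_proteins, 2 * samples_per_class, seed=rs)
        complexes = random_complexes(matrix.index, n_complexes, seed=cxs)
        classes = pd.Series(labels, index=matrix.columns, name="class")
        for m in methods:
            res = resolve_method(m, alpha=alpha)(matrix, classes, complexes)
            if m in DIRECTIONAL_METHODS:
                rate = 0.5 * (
                    float((res["p_up_class1"] < alpha).mean())
                    + float((res["p_up_class2"] < alpha).mean())
                )
            else:
                rate = float(res["selected"].mean())
            per_round[m].append(rate)
    rows = []
    for m in methods:
        rates = np.asarray(per_round[m])
        rows.append(
            {
                "method": m,
                "rate": float(rates.mean()),
                "mc_se": float(rates.std(ddof=1) / np.sqrt(len(rates))),
                "n_rounds": n_rounds,
                "per_direction": m in DIRECTIONAL_METHODS,
            }
        )
    return pd.DataFrame(rows)


def fscore_benchmark(
    methods: Sequence[str] = ("ffishnet", "he", "gsea", "pfsnet", "fsnet"),
    n_datasets: int = 20,
    purity: float = 0.5,
    n_proteins: int = 1000,
    samples_per_class: int = 6,
    n_complexes: int = 62,
    alpha: float = 0.05,
    seed: int | None = None,
) -> pd.DataFrame:
    """F-scores of each method over replicate spiked datasets.

    Each dataset follows the standard spike-in design (20% differential
    proteins, effect sizes {0.2, 0.5, 0.8, 1.0, 2.0} applied to one class)
    with ``n_complexes`` differential and ``n_complexes`` non-differential
    pseudo-complexes at the given purity.  Returns one row per dataset and
    method with precision, recall and F.
    """
    rows = []
    for d, ds_seed in enumerate(_child_seeds(seed, n_datasets)):
        dataset, complexes = simulate_dataset(
            n_proteins=n_proteins, samples_per_class=samples_per_class,
            n_complexes=n_complexes, purity=purity, seed=ds_seed,
        )
        for m in methods:
            res = resolve_method(m, alpha=alpha)(dataset.matrix, dataset.classes, complexes)
            pr = precision_recall_f(res.loc[res["selected"], "complex_id"], complexes.truth or {})
            rows.append(
                {
                    "dataset": d, "method": m, "precision": pr.precision,
                    "recall": pr.recall, "f_score": pr.f_score,
                }
            )
    return pd.DataFrame(rows)


def stability_contrast(
    methods: Sequence[str] = ("ffishnet", "fishnet"),
    size: int = 4,
    reps: int = 100,
    n_datasets: int = 5,
    purity: float = 0.75,
    dispersion: float = 0.5,
    n_proteins: int = 1000,
    samples_per_class: int = 6,
    n_complexes: int = 62,
    seed: int | None = None,
) -> dict[str, float]:
    """Mean pairwise Jaccard stability of each method over noisy datasets.

    Each dataset is a spiked simulation at the given purity with
    overdispersed counts (``dispersion`` is the per-cell lognormal sigma; the
    0.5 default is a moderate technical coefficient of variation of about
    50%, which makes abundance ranks genuinely unstable between samples).
    Per round, ``size`` samples per class are drawn and the method re-run;
    the per-dataset mean pairwise Jaccard of the selection sets is averaged
    over ``n_datasets`` replicate datasets.  Larger means the same complexes
    are selected across resamplings.
    """
    per_method: dict[str, list[float]] = {m: [] for m in methods}
    for pair in np.array_split(_child_seeds(seed, 2 * n_datasets), n_datasets):
        ds_seed, resample_seed = (int(s) for s in pair)
        dataset, complexes = simulate_dataset(
            n_proteins=n_proteins, samples_per_class=samples_per_class,
            n_complexes=n_complexes, purity=purity, seed=ds_seed, dispersion=dispersion,
        )
        for m in methods:
            mats = stability_resampling(
                dataset.matrix, dataset.classes, complexes, m,
                sizes=[size], reps=reps, seed=resample_seed,
            )
            per_method[m].append(mean_pairwise_jaccard(mats[size].data))
    return {m: float(np.mean(v)) for m, v in per_method.items()}


def cv_contrast(
    method: str = "ffishnet",
    reps: int = 200,
    n_proteins: int = 1000,
    samples_per_class: int = 12,
    effect_sizes: tuple[float, ...] = (1.0, 2.0),
    n_complexes: int = 62,
    seed: int | None = None,
) -> dict[str, float]:
    """Mean CV accuracy with real vs shuffled labels on a separable dataset.

    The dataset uses strong effect sizes (2x and 3x multipliers) so that the
    spiked complexes carry clear class signal, and 12 samples per class —
    the size of the renal-cancer study design (six tissue pairs measured in
    two technical batches) whose half/quarter/quarter CV protocol this
    mirrors.  A useful selector should give accuracy near 1 with real labels
    and near 0.5 with shuffled ones.
    """
    ds_seed, cv_seed_real, cv_seed_shuf = _child_seeds(seed, 3)
    dataset, complexes = simulate_dataset(
        n_proteins=n_proteins, samples_per_class=samples_per_class,
        spec=SimulationSpec(effect_sizes=effect_sizes),
        n_complexes=n_complexes, purity=1.0, seed=ds_seed,
    )
    out = {}
    for scenario, s in (("real", cv_seed_real), ("shuffled", cv_seed_shuf)):
        records = cross_validate(
            dataset.matrix, dataset.classes, complexes, method,
            reps=reps, seed=s, scenario=scenario,
        )
        out[scenario] = float(records["accuracy"].mean())
    return out


def fpr_null(
    method: str = "ffishnet",
    reps: int = 100,
    n_proteins: int = 1000,
    n_samples: int = 12,
    n_complexes: int = 60,
    seed: int | None = None,
) -> float:
    """Mean pseudo-class false-positive rate on a homogeneous matrix."""
    seed_matrix, seed_cplx, seed_rounds = _child_seeds(seed, 3)
    matrix = synthesize_base_matrix(n_proteins, n_samples, seed=seed_matrix)
    complexes = random_complexes(matrix.index, n_complexes, seed=seed_cplx)
    rates = false_positive_eval(matrix, complexes, method, reps=reps, seed=seed_rounds)
    return float(rates["rate"].mean())
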