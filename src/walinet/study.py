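"""Desk-scale simulation study: train the network, compare baselines.

The study mirrors the standard evaluation protocol: metabolite spectra
are combined with nuisance signals from synthetic subjects, the network
is trained on one set of subjects, and removal quality is measured on
spectra from held-out subjects as range-restricted NRMSE against the
known metabolite ground truth.  Baselines are the conventional lipid-L2
operator (beta calibrated to the 0.938 setpoint on the evaluation
subject's own lipid basis) and HLSVD water removal followed by L2.

The scaled preset keeps the published architecture (depth 4, kernel 7,
dropout 0.01) at half the channel width and shrinks the sample and
epoch counts so the whole study runs in minutes on one CPU core; the
full preset mirrors the published configuration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .axis import AXIS_3D, SpectralAxis
from .hlsvd import remove_water
from .model import TrainConfig, YNet, YNetConfig, infer_nuisance_batch, train
from .nuisance import NuisanceParams, TrainingDataset, assemble_training_set
from .postproc import RANGE_FULL, RANGE_LIPID, RANGE_METAB, nrmse_batch
from .spectrum import Spectrum
from .spin_sim import MetaboliteRanges, build_basis, load_catalog

__all__ = ["StudyPreset", "SCALED_PRESET", "FULL_PRESET", "run_study", "StudyResult"]


@dataclass(frozen=True)
class StudyPreset:
    """Problem sizes and hyperparameters of one simulation study."""

    n_train: int = 6000
    n_eval: int = 1000
    n_train_subjects: int = 20
    n_eval_subjects: int = 4
    # per-subject lipid basis size, matching the scalp-voxel counts of
    # the acquisition geometries (the operator uses every scalp voxel)
    n_basis_spectra: int = 200
    base_channels: int = 8
    epochs: int = 15
    batch_size: int = 32
    mode: str = "walinet"
    # Desk-scale optimization: at batch size 32 the published lr of 0.01
    # is unstable; the scaled preset uses a lower rate with the same
    # quarter-decay applied over thirds of the epoch budget.
    lr: float = 3e-3
    grad_clip: float = 5.0
    lr_decay_epochs: int | None = None  # None: thirds of the epoch budget

    @property
    def lr_decay_every(self) -> int:
        if self.lr_decay_epochs is not None:
            return self.lr_decay_epochs
        return max(2, self.epochs // 3)


#: Desk-scale preset used by the test suite and the acceptance script.
SCALED_PRESET = StudyPreset()

#: Configuration mirroring the published training (GPU scale).
FULL_PRESET = StudyPreset(
    n_train=1_900_000,
    n_eval=100_000,
    n_train_subjects=19,
    n_eval_subjects=1,
    base_channels=16,
    epochs=400,
    batch_size=64,
    lr=0.01,
    lr_decay_epochs=50,
)


@dataclass
class StudyResult:
    """Per-spectrum NRMSE distributions and their summaries."""

    nrmse: dict[str, dict[str, np.ndarray]]
    history: list[dict]
    preset: StudyPreset
    network: "YNet | None" = None

    def quantile(self, method: str, range_name: str, q: float) -> float:
        return float(np.quantile(self.nrmse[method][range_name], q))

    def median(self, method: str, range_name: str) -> float:
        return self.quantile(method, range_name, 0.5)

    def reduction_vs(self, method: str, baseline: str, range_name: str) -> float:
        """Relative reduction (%) of the median NRMSE versus a baseline."""
        return 100.0 * (
            1.0 - self.median(method, range_name) / self.median(baseline, range_name)
        )

    def summary(self) -> dict:
        out: dict = {}
        for method, ranges in self.nrmse.items():
            out[method] = {
                name: {
                    "q25": float(np.quantile(v, 0.25)),
                    "median": float(np.quantile(v, 0.5)),
                    "q75": float(np.quantile(v, 0.75)),
                }
                for name, v in ranges.items()
            }
        return out


_RANGES = {"full": RANGE_FULL, "metab": RANGE_METAB, "lipid": RANGE_LIPID}


def _evaluate_methods(
    network: YNet, eval_set: TrainingDataset, n_components: int = 32
) -> dict[str, dict[str, np.ndarray]]:
    """NRMSE of the network and both conventional baselines."""
    axis = eval_set.axis
    truth = eval_set.metabolite_truth()
    n = len(eval_set)
    preds: dict[str, np.ndarray] = {
        "walinet": np.empty_like(eval_set.x1),
        "l2": np.empty_like(eval_set.x1),
        "hlsvd_l2": np.empty_like(eval_set.x1),
    }
    for sid in np.unique(eval_set.subject_ids):
        sel = np.flatnonzero(eval_set.subject_ids == sid)
        sub = eval_set.subspaces[int(sid)]
        x1 = eval_set.x1[sel]
        y = infer_nuisance_batch(network, x1, sub)
        preds["walinet"][sel] = x1 - y
        preds["l2"][sel] = sub.apply(x1.T).T
        for row, i in enumerate(sel):
            dewater = remove_water(
                Spectrum(x1[row], axis, "freq"), n_components=n_components
            ).to_freq()
            preds["hlsvd_l2"][i] = sub.apply(dewater.data)
    out: dict[str, dict[str, np.ndarray]] = {}
    for method, pred in preds.items():
        out[method] = {
            name: nrmse_batch(pred, truth, rng_ppm, axis)
            for name, rng_ppm in _RANGES.items()
        }
    return out


def run_study(
    seed: int = 0,
    preset: StudyPreset = SCALED_PRESET,
    axis: SpectralAxis = AXIS_3D,
    params: NuisanceParams | None = None,
    ranges: MetaboliteRanges | None = None,
    callback=None,
    network: YNet | None = None,
) -> StudyResult:
    """Generate data, train the network, evaluate all methods.

    Training and evaluation subjects are disjoint by construction
    (separate id blocks and RNG streams derived from ``seed``).  An
    already-trained ``network`` can be supplied to skip training.
    """
    params = params or NuisanceParams()
    systems, rel_conc = load_catalog()
    basis = build_basis(systems, axis)
    train_set = assemble_training_set(
        preset.n_train,
        preset.mode,
        basis,
        rel_conc,
        params=params,
        ranges=ranges,
        n_subjects=preset.n_train_subjects,
        n_basis_spectra=preset.n_basis_spectra,
        seed=seed * 2 + 1,
        subject_id_offset=0,
    )
    eval_set = assemble_training_set(
        preset.n_eval,
        preset.mode,
        basis,
        rel_conc,
        params=params,
        ranges=ranges,
        n_subjects=preset.n_eval_subjects,
        n_basis_spectra=preset.n_basis_spectra,
        seed=seed * 2 + 2,
        subject_id_offset=10_000,  # held-out subject block
    )
    history: list[dict] = []
    if network is None:
        network = YNet(YNetConfig(base_channels=preset.base_channels), seed=seed)
        config = TrainConfig(
            epochs=preset.epochs,
            batch_size=preset.batch_size,
            seed=seed,
            mode=preset.mode,
            lr=preset.lr,
            lr_decay_every=preset.lr_decay_every,
            grad_clip=preset.grad_clip,
        )
        network, history = train(network, train_set, config, callback=callback)
    nrmse = _evaluate_methods(network, eval_set)
    return StudyResult(nrmse=nrmse, history=history, preset=preset, network=network)
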