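"""Identification experiments: five-fold cross-validation and the two
ablation protocols (uniform channel reduction; brain-region removal).

The pipeline per window is: instantaneous phases -> PLV matrix -> density
sparsification -> (for the virtual-node model) augmented graph ->
renormalised operator -> classifier. PLV matrices are computed once per
window and reused across models, folds and ablations (ablation slices the
channel rows/columns before re-sparsifying).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedGroupKFold, StratifiedKFold

from .connectivity import PLVMatrix, instantaneous_phase, plv_matrix_from_phases, sparsify
from .models import TrainConfig, build_model, predict, renormalized_operator, train
from .montage import (
    REGION_NAMES,
    GroupScheme,
    Montage,
    ReductionLayout,
    assign_groups,
    load_montage,
    reduce_channels,
    remove_region,
)
from .synthetic import SyntheticCohort
from .virtual_graph import build_augmented_graph, restrict_groups

__all__ = [
    "CVResult",
    "AblationTable",
    "WindowedCohort",
    "windows_from_cohort",
    "model_inputs",
    "run_cv",
    "run_channel_reduction",
    "run_region_removal",
    "report",
]


@dataclass(frozen=True)
class CVResult:
    """Per-fold accuracies of one cross-validated model."""

    model: str
    fold_accuracies: tuple
    condition: str = ""

    @property
    def mean(self) -> float:
        return float(np.mean(self.fold_accuracies))

    @property
    def std(self) -> float:
        return float(np.std(self.fold_accuracies, ddof=1)) if len(self.fold_accuracies) > 1 else 0.0

    def as_percent(self) -> str:
        return f"{100 * self.mean:.2f} ± {100 * self.std:.2f}"


@dataclass
class AblationTable:
    """Rows keyed by (condition, model) -> CVResult (+ optional baseline drop)."""

    kind: str  # "channel_reduction" | "region_removal"
    rows: dict = field(default_factory=dict)  # (key, model) -> CVResult
    baselines: dict = field(default_factory=dict)  # model -> CVResult

    def drop(self, key, model_name: str) -> float:
        """Accuracy drop vs. the unablated baseline of the same model."""
        return self.baselines[model_name].mean - self.rows[(key, model_name)].mean


@dataclass
class WindowedCohort:
    """Windowed cohort with precomputed per-window PLV matrices."""

    plv: np.ndarray  # (n_windows, n_ch, n_ch) float32
    labels: np.ndarray  # (n_windows,) int
    subject_ids: list
    montage: Montage
    fs: float
    block_ids: np.ndarray = None  # (n_windows,) source-recording index


def windows_from_cohort(
    cohort: SyntheticCohort,
    montage: "Montage | None" = None,
    window_s: float = 1.0,
    overlap: float = 0.5,
) -> WindowedCohort:
    """Cut every recording into windows and compute each window's PLV matrix.

    Phases are extracted once per recording (the Hilbert transform of the
    full signal) and sliced per window, avoiding per-window edge effects
    and recomputation.
    """
    if montage is None:
        n = cohort.recordings[0].n_channels
        montage = load_montage("physionet64") if n == 64 else None
    ids = sorted({r.subject_id for r in cohort.recordings})
    id_to_label = {sid: i for i, sid in enumerate(ids)}
    mats, labels, blocks = [], [], []
    for rec_idx, rec in enumerate(cohort.recordings):
        phases = instantaneous_phase(rec.data)
        win = int(round(rec.fs * window_s))
        hop = max(1, int(round(win * (1.0 - overlap))))
        n_ep = (rec.n_samples - win) // hop + 1
        for i in range(n_ep):
            seg = phases[:, i * hop : i * hop + win]
            mats.append(plv_matrix_from_phases(seg).values.astype(np.float32))
            labels.append(id_to_label[rec.subject_id])
            blocks.append(rec_idx)
    return WindowedCohort(
        plv=np.stack(mats),
        labels=np.asarray(labels, dtype=int),
        subject_ids=ids,
        montage=montage,
        fs=cohort.recordings[0].fs,
        block_ids=np.asarray(blocks, dtype=int),
    )


def model_inputs(
    wc: WindowedCohort,
    model_name: str,
    groups: "GroupScheme | None" = None,
    layout: "ReductionLayout | None" = None,
    density: float = 0.2,
    w_virtual: float = 1.0,
) -> np.ndarray:
    """Per-window classifier inputs for one architecture.

    GCN variants receive the (m, m) renormalised operator per window;
    ``cnn_fc`` receives the sparse PLV matrix as a one-channel image.
    Channel ablation (``layout``) slices the PLV block before the density
    rule is re-applied on the kept channels.
    """
    n_all = wc.plv.shape[1]
    kept = np.asarray(layout.kept, int) if layout is not None else np.arange(n_all)
    if groups is None and model_name == "vn_gcn":
        groups = assign_groups(wc.montage, g=8)
    out = []
    for P in wc.plv:
        sub = PLVMatrix(values=P[np.ix_(kept, kept)].astype(float))
        sp = sparsify(sub, density=density)
        if model_name == "vn_gcn":
            grp = restrict_groups(groups, tuple(kept))
            graph = build_augmented_graph(sp, grp, w_virtual=w_virtual)
            out.append(renormalized_operator(graph.adjacency).L_sym.astype(np.float32))
        elif model_name == "tinas_gcn":
            out.append(renormalized_operator(sp.values).L_sym.astype(np.float32))
        elif model_name == "cnn_fc":
            img = np.zeros((n_all, n_all), dtype=np.float32)
            img[np.ix_(kept, kept)] = sp.values
            out.append(img)
        else:
            raise ValueError(f"unknown model {model_name!r}")
    return np.stack(out)


def run_cv(
    inputs: np.ndarray,
    labels: np.ndarray,
    model_name: str,
    n_folds: int = 5,
    cfg: "TrainConfig | None" = None,
    seed: int = 0,
    condition: str = "",
    split_mode: str = "per-window",
    block_ids: "np.ndarray | None" = None,
) -> CVResult:
    """Stratified k-fold cross-validation, one freshly built model per fold.

    Folds are stratified by subject so every subject appears in every test
    fold. The default split is per-window; ``split_mode="per-block"`` keeps
    all windows of one source recording (``block_ids``) on the same side of
    each fold, a stricter protocol when windows overlap in time.
    Deterministic given the seed.
    """
    labels = np.asarray(labels, dtype=int)
    counts = np.bincount(labels)
    if counts[counts > 0].min() < n_folds:
        raise ValueError(f"every subject needs at least {n_folds} windows")
    cfg = cfg or TrainConfig(seed=seed)
    n_classes = int(labels.max()) + 1
    m = inputs.shape[1]
    if split_mode == "per-window":
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
        splits = skf.split(np.zeros(len(labels)), labels)
    elif split_mode == "per-block":
        if block_ids is None:
            raise ValueError("per-block split needs block_ids")
        sgk = StratifiedGroupKFold(n_splits=n_folds, shuffle=True, random_state=seed)
        splits = sgk.split(np.zeros(len(labels)), labels, groups=block_ids)
    else:
        raise ValueError(f"unknown split_mode {split_mode!r}")
    accs = []
    for fold, (tr, te) in enumerate(splits):
        model = build_model(model_name, n_classes=n_classes, m=m, seed=seed + fold)
        train(model, inputs[tr], labels[tr], cfg)
        pred, _ = predict(model, inputs[te])
        accs.append(float(np.mean(pred == labels[te])))
    return CVResult(model=model_name, fold_accuracies=tuple(accs), condition=condition)


def run_channel_reduction(
    wc: WindowedCohort,
    model_names=("vn_gcn",),
    ks=(56, 48, 40, 32, 24, 16),
    cfg: "TrainConfig | None" = None,
    density: float = 0.2,
    seed: int = 0,
) -> AblationTable:
    """CV accuracy after uniformly thinning the montage to each k."""
    groups = assign_groups(wc.montage, g=8)
    table = AblationTable(kind="channel_reduction")
    for name in model_names:
        base_inputs = model_inputs(wc, name, groups=groups, density=density)
        table.baselines[name] = run_cv(
            base_inputs, wc.labels, name, cfg=cfg, seed=seed, condition="full"
        )
        for k in ks:
            if k == wc.montage.n_channels:
                table.rows[(k, name)] = table.baselines[name]
                continue
            layout = reduce_channels(wc.montage, k)
            inp = model_inputs(wc, name, groups=groups, layout=layout, density=density)
            table.rows[(k, name)] = run_cv(
                inp, wc.labels, name, cfg=cfg, seed=seed, condition=f"k={k}"
            )
    return table


def run_region_removal(
    wc: WindowedCohort,
    model_names=("vn_gcn",),
    regions=REGION_NAMES,
    cfg: "TrainConfig | None" = None,
    density: float = 0.2,
    seed: int = 0,
) -> AblationTable:
    """CV accuracy after removing each scalp region, with drop vs. baseline."""
    groups = assign_groups(wc.montage, g=8)
    table = AblationTable(kind="region_removal")
    for name in model_names:
        base_inputs = model_inputs(wc, name, groups=groups, density=density)
        table.baselines[name] = run_cv(
            base_inputs, wc.labels, name, cfg=cfg, seed=seed, condition="full"
        )
        for region in regions:
            layout = remove_region(wc.montage, region)
            inp = model_inputs(wc, name, groups=groups, layout=layout, density=density)
            table.rows[(region, name)] = run_cv(
                inp, wc.labels, name, cfg=cfg, seed=seed, condition=region
            )
    return table


def report(results, manifest: "dict | None" = None) -> str:
    """Render results as a markdown table (accuracies in %, two decimals).

    Accepts a CVResult, an AblationTable, or a list of CVResults; returns
    the markdown text. An empty input yields an explicit no-results note.
    """
    lines = []
    if results is None or (isinstance(results, (list, tuple)) and len(results) == 0):
        lines.append("No results.")
    elif isinstance(results, CVResult):
        lines.append("| Model | ACC(%) |")
        lines.append("| --- | --- |")
        lines.append(f"| {results.model} | {results.as_percent()} |")
    elif isinstance(results, AblationTable):
        has_drop = bool(results.baselines)
        head = "| Condition | Model | ACC(%) |" + (" Drop(%) |" if has_drop else "")
        lines.append(head)
        lines.append("| --- | --- | --- |" + (" --- |" if has_drop else ""))
        for (key, model), res in results.rows.items():
            row = f"| {key} | {model} | {res.as_percent()} |"
            if has_drop:
                row += f" {100 * results.drop(key, model):.2f} |"
            lines.append(row)
    else:
        lines.append("| Model | Condition | ACC(%) |")
        lines.append("| --- | --- | --- |")
        for res in results:
            lines.append(f"| {res.model} | {res.condition} | {res.as_percent()} |")
    if manifest:
        import json

        lines.append("")
        lines.append("```json")
        lines.append(json.dumps(manifest, indent=2, sort_keys=True, default=str))
        lines.append("```")
    return "\n".join(lines) + "\n"
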