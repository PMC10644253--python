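# vnfc — virtual-node functional connectivity for EEG person identification

EEG functional-connectivity (FC) networks are individual-specific: the
pattern of statistical coupling between electrode signals can identify who
produced a recording. Plain FC graphs, however, ignore *where* the
electrodes sit, which makes the resulting biometrics brittle when channels
are missing. `vnfc` implements an FC network that fuses spatial structure
into the graph: the 64 electrodes of the 10-10 montage are partitioned into
8 spatial groups, each group is attached to a **local virtual node**, and a
single **global virtual node** connects the locals — a 73-node graph whose
real-real edges are phase-locking values (PLV) and whose virtual edges
encode the montage geometry. A small graph convolutional network (VN-GCN)
classifies which subject produced each 1 s window of signal.

The package is for researchers working on EEG biometrics and
connectivity-based classification who want a complete, reproducible,
CPU-only reference pipeline: montage handling, windowing, PLV graphs,
virtual-node augmentation, the GCN and two baselines, the channel-reduction
and region-removal ablation protocols, and a synthetic phase-coupled cohort
generator so that everything is testable without downloading datasets.

## The model

For channels x, y with instantaneous phases φₓ(t), φᵧ(t) (analytic-signal
angle) over a window of T samples:

    PLV(x, y) = | T⁻¹ Σₜ exp(i(φₓ(t) − φᵧ(t))) |  ∈ [0, 1]

The n×n PLV matrix is sparsified (default: keep the top 20% of edges) and
augmented with g local + 1 global virtual nodes (m = n + g + 1 = 73 for the
default montage). With Ã = A + I and D̃ the degree of Ã, graph convolutions
use the renormalised operator and the layer rule

    L̃_sym = D̃^{−1/2} Ã D̃^{−1/2},     X_{k+1} = σ(L̃_sym X_k W_k + b_k)

with per-node bias b_k ∈ R^{m×out}. The VN-GCN is two graph convolutions
(widths 32, 8) → flatten (584) → dense → softmax, trained by categorical
cross-entropy; it has 67,965 parameters (68.0 k). The baselines are the same
GCN on the bare 64-node graph (59.8 k) and a CNN that reads the PLV matrix
as an image (785.2 k). Everything runs on numpy; no GPU or deep-learning
framework is required.

## Worked example

```python
import numpy as np
from vnfc import (assign_groups, build_augmented_graph, load_montage,
                  plv_matrix, sample_subject, simulate_recording,
                  sliding_windows, sparsify)

montage = load_montage("physionet64")
subject = sample_subject(n_channels=64, coupling_density=0.02, seed=1)
recording = simulate_recording(subject, duration_s=10.0, fs=160.0, seed=2)
window = sliding_windows(recording, window_s=1.0, overlap=0.5)[0]

plv = plv_matrix(window)
iu = np.triu_indices(64, k=1)
coupled = subject.coupling[iu] > 0
print(f"coupled pairs:   {plv.values[iu][coupled].mean():.3f}")
print(f"uncoupled pairs: {plv.values[iu][~coupled].mean():.3f}")

graph = build_augmented_graph(sparsify(plv, density=0.2), assign_groups(montage, g=8))
print(graph.adjacency.shape)
```

prints

```
coupled pairs:   0.814
uncoupled pairs: 0.329
(73, 73)
```

The subject's truly coupled oscillator pairs phase-lock (PLV ≈ 0.81 in a
single 1 s window) while uncoupled pairs sit near the finite-window noise
floor (≈ 0.33), and the augmented adjacency has the expected 73 nodes.
`examples/` contains narrative scripts for each capability — graph
construction (`01`), architecture accounting (`02`), cross-validated
identification with a chance control (`03`), and both ablation protocols
(`04`). A thin CLI mirrors the library:

```bash
vnfc architecture --model vn_gcn
vnfc simulate --subjects 5 --runs 2 --duration 20 --seed 7 --out cohort.h5
vnfc experiment --cohort cohort.h5 --mode cv --out manifest.json
```

Real EDF recordings are ingested with `vnfc.read_edf(path, montage)`, which
orders channels to the montage and feeds the same pipeline.

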