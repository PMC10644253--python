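"""Layer shapes and exact parameter counts of the three classifiers.

Builds the virtual-node GCN, the plain 64-node GCN baseline, and the
CNN baseline that reads the PLV matrix as an image, and prints each
model's layer budget. The totals (68.0 k / 59.8 k / 785.2 k) are fixed by
the architecture, independent of any training.
"""

from vnfc import build_model, count_parameters
from vnfc.models import kilo

for name in ("vn_gcn", "tinas_gcn", "cnn_fc"):
    model = build_model(name, n_classes=109)
    print(f"\n{name}  (flatten length {model.flatten_length})")
    for layer, shape in model.layer_shapes().items():
        print(f"  {layer:14s} -> {shape}")
    for layer, count in model.parameter_breakdown().items():
        print(f"  {layer:14s} {count:>8,d} parameters")
    total = count_parameters(model)
    print(f"  total          {total:>8,d}  ({kilo(total)} k)")
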