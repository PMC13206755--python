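"""Build the canonical model and account for every tunable parameter.

The encoder backbone (ViT-large: 24 blocks, width 1024) is frozen; training
touches only the adapters, decoder, skip branches and Post-adapter.  The
printout shows where the ~35.6 M tunable parameters live — the decoder and
the per-block bottleneck adapters dominate.
"""

from collections import Counter

from fundusseg import ModelConfig, build_model, count_frozen_parameters, \
    count_tunable_parameters

model = build_model(ModelConfig.canonical(num_classes=3), seed=112316)

per_module = Counter()
for name, p in model.named_parameters():
    if not p.frozen:
        per_module[name.split(".")[0]] += p.data.size

print(f"{'module':16s}{'tunable parameters':>20s}")
for module, n in per_module.most_common():
    print(f"{module:16s}{n:>20,}")
tunable = count_tunable_parameters(model)
print(f"{'total':16s}{tunable:>20,}  ({tunable / 1e6:.2f} M)")
print(f"{'frozen encoder':16s}{count_frozen_parameters(model):>20,}")
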