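# awcop — adaptive-weight multimodal fusion for coronary stenosis risk

Coronary artery stenosis of ≥ 75% is the conventional threshold for
percutaneous intervention, but confirming it requires coronary CT
angiography, which is invasive and not suitable for every patient. `awcop`
implements a non-invasive alternative: a late-fusion neural network that
predicts the binary endpoint (stenosis ≥ 75% vs < 75%) from four modalities
a clinician can collect at the bedside —

* a **tongue image** (traditional tongue-diagnosis view; the coating region
  carries most of the signal),
* a **face image** (forehead, nose and cheek microcirculation),
* a **radial pulse pressure waveform** (30 s at 50 Hz), and
* a **clinical lab panel** (50 features, screened to the most informative 15).

## The model

Each modality gets its own encoder producing a 128-dimensional embedding
**e**ₘ:

* images: 3×3 conv (3→64) → BN → ReLU → 2×2 max-pool → four 64-channel
  residual blocks → global average pool → FC 64→128 → single-head
  self-attention over the embedding split into 8 tokens;
* pulse: single-layer LSTM (hidden width 64) over the 300-sample stable 6-s
  segment, final hidden state → FC 64→128;
* labs: FC 15→128 with ReLU over the 15 random-forest-screened features.

The decision layer learns one raw scalar aₘ per modality, normalizes
wₘ = softmax(a)ₘ, and fuses by weight-scaled concatenation

  z = [w_t·e_t ‖ w_f·e_f ‖ w_p·e_p ‖ w_c·e_c] ∈ ℝ⁵¹²,

followed by a dense head to 2 logits. Training minimizes class-weighted
cross-entropy plus λ·R with the regularizer R = Σₘ aₘ², so the weights stay
near the simplex center unless a modality earns its influence. Five simpler
decision layers (concat, max, mean, sum, attention) and seven module /
seven modality ablations reproduce the full comparison protocol, and
Grad-CAM (images) plus input-gradient saliency with top-20% marking (pulse)
provide the interpretability layer.

Because clinical recordings of this kind are not publicly available, the
package ships a first-class synthetic-cohort generator with known ground
truth (planted coating-hue, facial-brightness, pulse-morphology and lab
effects) so every stage is testable end to end; see `docs/methods.md` for
what the generator does and does not emulate.

## Worked example

```python
import numpy as np
from awcop import (CohortSpec, generate_cohort, assemble_dataset, TrainSpec,
                   train, evaluate)

spec = CohortSpec(n_patients=120, prevalence=0.5, seed=7, image_size=(16, 16))
manifest, truth = generate_cohort(spec, "cohort/")
dataset = assemble_dataset(manifest, image_size=(16, 16), seed=7)

clf = train(dataset, TrainSpec(epochs=15, batch_size=16, seed=7))
print("fusion weights (tongue, face, pulse, clinical):",
      np.round(clf.fusion_weights_, 3))
for split in ("internal", "external"):
    rep = evaluate(clf, dataset, split)
    print(f"{split}: AUC={rep.auc:.3f} ACC={rep.acc:.3f} "
          f"F1={rep.f1:.3f} Recall={rep.recall:.3f} (n={rep.n})")
```

prints

```
fusion weights (tongue, face, pulse, clinical): [0.253 0.252 0.248 0.247]
internal: AUC=1.000 ACC=1.000 F1=1.000 Recall=1.000 (n=18)
external: AUC=1.000 ACC=1.000 F1=1.000 Recall=1.000 (n=18)
```

The default synthetic effects are strong enough that the 120-patient cohort
is essentially separable — the perfect held-out metrics say the pipeline
works, not that the clinical problem is easy. The fusion weights stay near
0.25 because every modality carries signal; planting signal in a single
modality shifts weight toward it.

The same stages are available from the shell:

```bash
awcop simulate --out cohort --seed 7 --n-patients 120
awcop pulse-features --manifest cohort/manifest.csv --out features.csv
awcop screen         --manifest cohort/manifest.csv --out screen.csv
awcop train          --manifest cohort/manifest.csv --out model --image-size 16 --epochs 15
awcop evaluate       --manifest cohort/manifest.csv --checkpoint model --split internal
awcop ablate         --manifest cohort/manifest.csv --kind fusion --out fusion.csv --image-size 16
awcop explain        --checkpoint model --manifest cohort/manifest.csv --patient P0001 --out explain/
awcop run            --config run.yaml        # staged, seeded, hash-manifested
```

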