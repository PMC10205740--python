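# epiderm

Quantification of UV-induced cell damage in stained epidermis histology.

Pathologists grade DNA damage in immunohistochemically stained skin
sections (CPD / 6-4PP photoproduct stains on human skin, skin models and
porcine ear skin) by the ratio of damaged to total nuclei,
`S_nuclei = N_dmg / N_all`. That score is cheap to annotate but noisy —
on slides with spatially heterogeneous damage, two experts can disagree
by 0.2 on a [0, 1] scale. This package implements the area-based
alternative `S_area = A_dmg / A_epi` (damaged-pixel area over total
epidermis-pixel area, from a 3-class segmentation mask), the estimators
that predict both scores from images, and the statistics used to compare
them against human agreement:

- a **3-class U-Net family** (base widths 16/32/64) with sliding-window
  full-image inference, from which S_area is an exact pixel tally;
- a **VGG16-style score regressor** (plain, or *masked* — input restricted
  to the epidermis by a separately trained binary U-Net);
- a **synthetic stained-epidermis generator** with exact ground-truth
  masks, nuclei and scores, plus a calibratable noisy-annotator model, so
  the whole pipeline is testable without any download;
- **evaluation machinery**: stratified 10-fold CV (by staining, tissue and
  mask availability), macro-averaged IoU over the three classes, MAE
  statistics, and the 1000-replicate paired bootstrap that compares
  model-vs-pathologist against pathologist-vs-pathologist agreement.

The networks run on a small in-package numpy stack (`epiderm.nn`) with
verified gradients — no deep-learning framework required. See
`docs/methods.md` for the full model and design notes.

## Worked example

```python
import numpy as np
from epiderm import (GeneratorConfig, generate_sample, s_area_from_mask,
                     macro_iou, mae_stats)

# one synthetic stained field: 256x256 px at 0.645 um/px, 30% damage target
sample = generate_sample(GeneratorConfig(target_damage_fraction=0.3,
                                         heterogeneity=0.5, seed=3))
pair, areas = s_area_from_mask(sample.mask)
print(f"S_area  = {pair.s_area:.4f}  (A_dmg={areas.a_dmg}, A_epi={areas.a_epi})")
print(f"S_nuclei= {sample.true_scores.s_nuclei:.4f}  ({len(sample.nuclei)} nuclei)")
```

prints

```
S_area  = 0.3000  (A_dmg=5713, A_epi=19042)
S_nuclei= 0.2188  (64 nuclei)
```

The damaged area is 30.00% of the epidermis — the generator hits its
target fraction exactly by thresholding its damage field at the matching
quantile — while the nucleus-based score (14 of 64 nuclei damaged) scatters
around it, exactly the weak-label noise the area score is meant to avoid.

Training the desk-scale U-Net/16 on 60 such samples and scoring 12
held-out ones (as `scripts/acceptance.py` does) reaches a held-out
macro-IoU around 0.87 and recovers S_area with an MAE around 0.01;
the score regressor trained on 80 samples predicts S_nuclei with an MAE
around 0.08 against a predict-the-mean baseline of roughly 0.27.

## Command line

```sh
epiderm synth --n 80 --out data/ --seed 42        # synthetic dataset
epiderm validate --manifest data/manifest.csv     # stratum counts, integrity
epiderm train-seg --manifest data/manifest.csv --width 16 --out run/
epiderm predict --model run/unet16_rep0.npz --image data/images/s0000.png \
    --width 16 --out mask.png                     # mask PNG + S_area JSON
epiderm bootstrap --a path1.csv --b path2.csv --n 1000 --seed 42 --out boot.json
epiderm cv --manifest data/manifest.csv --k 10    # stratified folds
epiderm run --dataset synthetic:smoke --task segmentation --out exp/
epiderm deposit-stats --deposit data/             # annotation statistics only
```

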