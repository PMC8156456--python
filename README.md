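# csag

Skin-lesion segmentation toolkit built around a **Channel-Spatial Fast
Attention-guided Filter (CSFAG)**: a fast guided filter whose per-window
ridge regression is weighted by squared attention values from fused
channel + spatial attention. The package provides

- the attention-guided filter itself (`csag.csfag`), with an O(N)
  box-sum production path and an independent brute-force oracle,
- channel / spatial attention gates and their fusion (`csag.attention`),
- a densely connected bottleneck (`csag.dense`),
- five segmentation network variants — `unet`, `mnet` (pyramid inputs +
  averaged side outputs), `mnet_dc`, `mnet_csfag`, `csag_dccnet` — with
  exact parameter accounting (`csag.network`),
- the preprocessing / 8x augmentation pipeline (`csag.preprocess`),
- a deterministic synthetic dermoscopy generator (`csag.synthetic`),
- confusion-matrix metrics with per-image table averaging (`csag.metrics`),
- CPU training / prediction orchestration (`csag.train`) and a CLI.

Everything runs on numpy: the package ships its own compact reverse-mode
autodiff engine (`csag.nn`) with conv / batch-norm / pooling / bilinear /
box-sum primitives, verified against finite differences.

The calibrated variant configs reproduce the published parameter budgets
exactly at printed rounding: 8.6M, 10.92M, 13.79M, 24.89M and 28.74M.

## CLI

```sh
csag synth --n 64 --seed 7 --out data/           # synthetic images+masks+manifest
csag params --variant csag_dccnet                # exact + rounded parameter count
csag train --config cfg.yaml --data data/        # momentum SGD training
csag predict --ckpt run.npz --in data/ --out preds/
csag evaluate --pred preds/ --gt data/ --out metrics.csv
csfag filter --guide g.png --input f.png --r 4 --lam 0.001 --out o.png
```

A minimal training YAML mirrors `TrainConfig` / `NetworkConfig`:

```yaml
epochs: 30
batch_size: 8
lr: 0.1
seed: 0
network:
  variant: csag_dccnet
  widths: [8, 16, 24, 32]
  bottleneck_out: 48
  pyramid_widths: [8, 8, 16]
  dense_growth: 16
  csfag_widths: [8, 8, 16, 16]
  image_size: 128
```

## Defaults from the published configuration

Filter window radius `r = 4`, regularizer `lam = 1e-3`; momentum SGD with
momentum 0.9, weight decay 5e-4, initial learning rate 0.1 multiplied by
0.9 every 50 epochs, mini-batch 16; two-class softmax heads; D = 3 dense
blocks in the bottleneck.
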