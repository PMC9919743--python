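# wristfall

Fall detection from wrist-worn accelerometers: sliding-window LSTM
classification with trailing-median smoothing, a layer-freezing transfer
learning protocol for small target datasets and heterogeneous devices,
dual-wrist ensemble fusion, person-aware evaluation, and a synthetic signal
generator so the whole pipeline runs end to end without any recorded data.

The neural network (LSTM, dense layers, batch normalisation, Adam,
backpropagation through time) is implemented in pure NumPy — no deep-learning
framework is required.

## Layout

| module | purpose |
| --- | --- |
| `wristfall.device_io` | device profiles (MSBAND / Huawei / meta-sensor), labelled CSV recordings, unit normalisation, resampling |
| `wristfall.labeling` | peak-centred fall-window relabelling, multi-peak location, ADL trimming, trial segmentation |
| `wristfall.windowing` | fixed-size data blocks, trailing-median smoothing, strict fall threshold |
| `wristfall.model` | baseline / improved LSTM classifier, training, inference, bundle serialization |
| `wristfall.transfer` | freeze-precursory-layers fine-tuning and the paired transfer-vs-scratch protocol |
| `wristfall.ensemble` | left/right wrist probability fusion and LOPO comparison |
| `wristfall.evaluation` | per-person 70/30 splits, leave-one-person-out folds, F1 / PR-AUC / traces |
| `wristfall.synthetic` | device-profiled synthetic fall and ADL recordings (scripted in continuous time, rendered per device) |
| `wristfall.cli` | `wristfall` command-line interface |

## CLI

```sh
# generate a synthetic dataset directory (CSV per subject/wrist/trial)
wristfall simulate --subjects 8 --device metasensor --wrists left,right \
    --seed 1 --out data/meta

# train a classifier from scratch
wristfall train --data data/meta --device metasensor --epochs 25 \
    --seed 1 --out models/meta

# fine-tune a pretrained bundle on another dataset (recurrent layer frozen)
wristfall transfer --base models/meta --data data/huawei --device huawei \
    --seed 1 --out models/huawei-tl

# evaluate (JSON report with F1, PR curve, AUC, prediction trace)
wristfall evaluate --model models/meta --data data/meta --device metasensor \
    --split 7030 --out reports/meta.json

# stream one recording -> per-block probability trace
wristfall predict --model models/meta --input data/meta/s01/left/fall-front_0.csv \
    --device metasensor --out trace.csv

# full paired transfer-vs-scratch comparison
wristfall protocol --source data/msband --target data/meta \
    --source-device msband --target-device metasensor --split lopo \
    --seed 1 --out reports/protocol.json
```

Every flag can also be given through a YAML config file (`--config`); explicit
flags win. All commands are deterministic given `--seed`.

## Data format

CSV with header `t_ms,x,y,z,label`, one dataset directory per device laid out
as `<dataset>/<subject>/<wrist>/<activity>_<trial>.csv`. Raw axis values are
multiplied by the device profile's `unit_scale` on read so that everything
downstream works in g.
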