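# netphys

Physiology-style analyses of convolutional-network activations: which
channels of a layer are selective for a stimulus category (e.g. faces),
how sparse and localized their code is, how similarly they represent
stimuli, and how well their activity explains brain responses.

## Who this is for

Researchers probing trained vision networks the way visual
neurophysiologists probe cortex — for example in *visual deprivation*
experiments, where a network is trained on a dataset from which every
face-containing image has been screened out and one asks whether
face-selective channels emerge anyway, and how their tuning differs from
a normally trained network's. `netphys` implements the full analysis
battery such a study needs, operating on exported activation tensors
(image × channel × height × width, post-ReLU) from any feed-forward
convolutional architecture, plus a synthetic-data module that plants
recoverable ground truth so every stage can be validated end to end
without any downloads.

## What it computes

**Dataset screening** (`netphys.screening`) — the deprivation-dataset
construction rules: remove every image flagged by *either* of two
raters, then drop categories whose remaining training images number
strictly fewer than a threshold (default 640).

**Channel selectivity** (`netphys.selectivity`) — a channel is a
candidate when the target category evokes its strictly highest mean
activation; candidacy is tested with a two-sided Mann-Whitney U test of
the per-image channel means (target vs. runner-up category), Bonferroni
corrected over all channels in the layer. Selectivity is quantified by
the *selective ratio* (target mean / highest non-target mean) and by
*lifetime sparseness*

S = ( Σᵢ rᵢ / n )² / ( Σᵢ rᵢ² / n )

on min–max normalized category means rᵢ; S ∈ (0, 1], smaller = more
selective (a one-hot profile gives 1/n).

**Representational similarity** (`netphys.representation`) — Fisher-z
transformed Pearson correlations between per-image channel-mean vectors;
within- and between-category summary means.

**Sparse coding & empirical receptive fields** (`netphys.coding`) —
counts of strictly-positive units per map, and the empirical receptive
field: per image, up-sample the channel map to input size, find the unit
whose theoretical receptive field contains the highest mean up-sampled
activation, crop that box, and average crops across images. Theoretical
receptive fields come from the standard kernel/stride/padding recursion
(`netphys.activations.theoretical_rf`) — 163 px with a 16-px grid stride
at the fifth convolution of the classic five-conv reference stack.

**Brain encoding models** (`netphys.brain_link`) — channel time series
→ log(x+1) → convolution with a double-gamma HRF peaking at 4 s →
down-sampling to the scanner TR → z-scoring; then per-vertex OLS R² maps,
averaged across stimulus clips, with top-k-contrast ROIs and a
complexity-matching rule for comparing networks with different numbers
of selective channels.

**Behavioral readout** (`netphys.behavior`) — two-layer transfer heads
(sigmoid hidden layer, softmax output) trained by SGD on frozen
features, and the face-inversion contrast (paired t on upright vs.
vertically flipped stimuli).

**Statistics** (`netphys.stats`) — paired t with Cohen's d, two-factor
fixed-effects ANOVA (type-II SS) with partial η² and simple effects,
Bonferroni correction.

**Synthetic ground truth** (`netphys.synthetic`) — generators for every
input above, with planted selective channels of controlled gain, known
vertex mixing weights, known rater flag rates, and a toy convolutional
network with an optional planted localized filter.

## Worked example

Plant two selective channels (gain 5 over baseline, noise sd 0.1) among
64 channels, 10 categories × 80 images, then recover them:

```python
from netphys.synthetic import PlantedSelectivitySpec, gen_activation_dataset
from netphys.selectivity import test_channels

spec = PlantedSelectivitySpec(channel_ids=(3, 11), target_category=0,
                              gain=5.0, noise_sd=0.1)
ds = gen_activation_dataset(n_categories=10, images_per_category=80,
                            n_channels=64, map_shape=(3, 3), spec=spec, seed=7)
report = test_channels(ds, target="cat000", alpha=0.05)
print(list(report.significant_channels))
print(report.frame[report.frame["significant"]]
      [["runner_up", "p_corrected", "selective_ratio", "sparseness"]].round(4))
```

prints

```
[3, 11]
        runner_up  p_corrected  selective_ratio  sparseness
channel
3          cat007          0.0           4.9567      0.1025
11         cat007         0.0           4.9705      0.1026
```

Exactly the planted pair is significant. The selective ratio ≈ 5
recovers the planted gain (target mean ≈ 5× the runner-up's), and the
lifetime sparseness ≈ 0.10 reflects a narrowly tuned profile — compare
1/n ≈ 0.10 for a perfectly one-hot profile over these 10 categories.

The same analyses are available from the shell:

```
netphys simulate --preset selectivity --seed 7 --out sim/
netphys selectivity --activations sim/activations.h5 --target cat000 --out sel/
netphys rsa --activations sim/activations.h5 --categories cat000,cat001 --out rsa/
```

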