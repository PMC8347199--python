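# hypospec

Chemometric discrimination of Raman micro-spectroscopy maps of hypothalamic
arcuate–median eminence (Arc-ME) tissue from control (CTRL) and
high-fat-diet (HFD) mice — built as a tested, reusable pipeline driven by a
synthetic-spectrum generator, for spectroscopists and chemometricians who
want to exercise or extend the workflow without access to raw tissue
spectra (none are publicly deposited for this study system).

The pipeline chains:

1. **Synthetic map generation** — Lorentzian band mixtures with
   class-dependent amplitudes for glycogen, collagen, lipid-ester,
   silent-zone cyanide (2248 cm⁻¹) and C–H bands, under a map-level
   5th-order fluorescence background 5–20× the band heights, plus
   exposure-averaged Gaussian noise. The noiseless profiles encode the
   lipid-saturation index I(1655)/I(1444) = 0.88 (CTRL) and 0.55 (HFD)
   exactly, overlap included.
2. **Two-stage baseline correction** — iterative 5th-order *modified
   polyfit* (refit to min(signal, fit)), then penalized **asymmetric least
   squares** (λ = 10⁵, p = 0.001, second-difference penalty, banded O(n)
   solve).
3. **Region selection and normalization** — fingerprint 500–1800 cm⁻¹ and
   high-wavenumber/silent-zone 2100–3100 cm⁻¹, then unit-area
   normalization over the retained (piecewise) grid and training-mean
   centering.
4. **Duplex splitting** — the deterministic distance-based duplex
   algorithm per class (default training fraction 5600/7409).
5. **PLS-DA** — hand-implemented NIPALS PLS1 on the dummy-coded response
   (HFD = 1), 0.5-threshold classification, 10-fold cross-validated
   latent-variable selection, VIP scores
   (VIP²_j averages to 1; VIP > 1 flags discriminant channels) and
   signed-coefficient region calling.
6. **Band analytics** — class averages with SD envelopes, prominence-based
   peak detection, assignment against the band library, and the 1655/1444
   saturation ratio.

## Worked example

The numbered drivers under `analysis/` run the study end to end and write
tables to `results/`:

```bash
python analysis/01_simulate.py            # 7409 x 3180 matrix, map summary
python analysis/02_preprocess_and_bands.py
python analysis/03_classify.py
```

`02_preprocess_and_bands.py` (1000 spectra per class) prints, among the
per-class peak tables:

```
CTRL: ratio 1655/1444 = 0.893
HFD:  ratio 1655/1444 = 0.578
```

— the corrected class averages recover the encoded saturation contrast
(lower ratio = more saturated lipid in the HFD class; the ~+0.03 offset is
the asymmetric-least-squares lower-envelope bias discussed in
`docs/methods.md`). The HFD peak table shows the ester-carbonyl band at
1748 cm⁻¹ and the glycogen band at 484 cm⁻¹ among its strongest features,
both absent or weaker for CTRL.

`03_classify.py` (2000 spectra per class, duplex split 3024/976) prints:

```
CV-selected latent variables: 1
test accuracy: CTRL=100.0%, HFD=100.0% (overall 100.0%)
discriminant regions (VIP > 1):
   1737.6- 1759.7 cm^-1  HFD-higher
   2235.7- 2259.9 cm^-1  HFD-higher
   ...
```

The VIP map flags exactly the bands whose class contrast the generator
encodes — in particular the silent-zone cyanide region around 2248 cm⁻¹
as HFD-higher. (Equal-amplitude C–H bands appear CTRL-higher after
unit-area normalization: the classic closure effect of normalizing
spectra whose total signal differs between classes.)

The same stages are scriptable via the CLI: `hypospec generate`,
`preprocess`, `split`, `train`, `run`, `report` (see `hypospec --help`).

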