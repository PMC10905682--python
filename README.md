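# lvifusion

Lymphovascular invasion (LVI) — tumor spread into lymphatic and blood
vessels — is a key preoperative finding in breast cancer: it predicts nodal
metastasis and often rules out breast-conserving surgery, yet it can only be
confirmed histologically after resection. `lvifusion` implements, end to
end, a framework for predicting LVI from preoperative multimodal breast MRI
in which prior clinico-radiological knowledge is injected directly into a 3D
convolutional network as extra image channels, together with the full
comparison stack such a study needs: a clinico-radiological logistic model,
a radiomics feature-selection chain, the image-only network ablation, and
DeLong-based ROC comparison. Because real LVI cohorts are private, the
package ships a synthetic cohort generator with known planted structure, so
every stage can be validated against ground truth.

## The model

Each case contributes three co-registered volumes (T1-weighted, T2-weighted,
contrast-enhanced T1-weighted analogues). After per-volume intensity
normalization (negatives clipped, then scaled to [0, 1]) a 32×32×32 patch is
cropped around the VOI center from each modality. Sixteen clinico-radiological
covariates x₁…x₁₆ (age, menopausal status, BI-RADS-style descriptors,
peritumoral edema, DWI rim sign, …), min-max scaled on the training set, are
broadcast into sixteen spatially constant 32³ planes. The network input is the
19-channel stack

    X = [patch_T1, patch_T2, patch_cT1, x₁·1, …, x₁₆·1] ∈ [0,1]^(19×32³)

The backbone is a compact 3D residual channel-attention CNN:

- head: 3³ conv (19→64 channels), BatchNorm3d, ReLU, factor-2 max pooling;
- four residual channel-attention blocks (RCAB), each
  y = x + CA(conv(ReLU(conv(x)))) with CA a squeeze-and-excitation gate
  σ(W₂ ReLU(W₁ GAP(x))) applied per channel;
- tail: 1³ conv (64→2), global average pooling, softmax over
  {LVI−, LVI+}.

Training uses class-weighted cross-entropy L = −w_y log p_y with
(w₋, w₊) = (0.25, 0.75) for the ~1:3 class imbalance, Adam (lr 10⁻⁴,
batch 48, 100 epochs at full scale), random flips along the three volume
axes as augmentation, and checkpoint selection at the minimum training loss
(minimum validation loss is available and used by the desk-scale
experiments). Dropping the 16 prior planes (3 input channels) gives the
matched image-only ablation. The layers — 3D convolution (FFT-based),
batch norm, pooling, channel attention, backprop and Adam — are implemented
in numpy; see `docs/methods.md`.

The baselines mirror standard practice: univariate logistic regression per
covariate (a binary covariate's OR equals the 2×2 cross-product ratio), a
p < 0.1 screen feeding a multivariate logistic model; and, for radiomics
tables, z-score normalization → univariate filter at p < 0.01 → greedy
|r| ≥ 0.90 correlation pruning → L1-penalized logistic regression with the
penalty chosen at the minimum 5-fold cross-validated deviance. Models are
compared by ROC AUC (Mann–Whitney with midrank ties), operating points at
the Youden index, and the paired DeLong test.

## Worked example

`examples/02_clinical_baseline.py` fits the clinical baseline to the
embedded reference-cohort counts (239 patients, 59 LVI-positive):

```
variable                                 OR           95% CI        p
peritumoral_edema                      7.54 ( 3.94, 14.42)    0.000
dwi_rim_sign                           4.31 ( 2.28,  8.12)    0.000
adjacent_vessel_sign                   2.10 ( 1.10,  4.01)    0.024
internal_enhancement                   1.76 ( 0.92,  3.34)    0.087
...
screened at p < 0.1: ['peritumoral_edema', 'internal_enhancement',
                      'adjacent_vessel_sign', 'dwi_rim_sign']
```

Peritumoral edema multiplies the odds of LVI about 7.5-fold and the DWI rim
sign about 4.3-fold; exactly four variables clear the p < 0.1 screen. The
other examples generate a cohort on disk (`01`), run the radiomics chain on
a synthetic feature table (`03`), train the fusion network and its ablation
(`04`), and produce the model-comparison table with DeLong p-values and an
ROC overlay (`05`). Each prints the numbers it computes and a line on what
they mean.

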