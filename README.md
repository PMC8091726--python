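# irfpquant

Objective quantification of near-infrared fluorescent (iRFP713) tumour
signal in raw TIFFs from small-animal in-vivo imaging platforms
(IVIS/Xenogen-class "XVI", Bruker-class "BIX", Li-Cor Pearl-class
"LPT"), for researchers tracking subcutaneous or deep-tissue xenograft
growth who want measurements that do not depend on each vendor's
subjective display gating.

## The model

A cropped raw image is treated as a 3-D intensity surface
`z(x, y) = I(x, y) / max I` with the maximum normalized to 1. A
horizontal **threshold plane** at level `t ∈ [0, 1]` cuts the surface:
pixels strictly above the plane are tumour signal, pixels at or below
are mouse-body / bed background. The initial level is chosen by Kapur
maximum-entropy thresholding — the cut that maximizes the summed
Shannon entropies of the below- and above-plane histogram partitions

    t* = argmax_t [ H(p | z ≤ t) + H(p | z > t) ]

— and can be overridden manually. All measurements are then taken from
the **raw, unscaled** counts: for a mask of area `A` pixels and plane
height `t·max I` in raw units,

    net_total = Σ_mask I(x, y) − (t · max I) · A

i.e. the plane height doubles as the per-pixel background estimate.
Because segmentation happens in normalized units, the mask is invariant
to any positive rescaling of the raw counts; because measurement
happens in raw units, `net_total` stays comparable across days imaged
at fixed settings.

Derived statistics: group-mean fold change between imaging days,
coefficient of variance (100·sd/mean, sample sd), dilution-series
log-log linearity and a k-sigma limit of detection, earliest-detection
tables, k×k sum-binning (an 8×8 bin multiplies per-pixel signal by 64),
saturation detection at the `2^bit_depth − 1` ceiling (16-bit for
XVI/BIX data, 22-bit for LPT), and the calliper volume
`(length × width²)/2`.

## Worked example

Generate a synthetic growth timecourse (a Gaussian tumour blob growing
exponentially at rate ln2/3.5 per day on a mouse-body plateau) and
quantify it with the automatic threshold:

```sh
irfpquant simulate --kind growth --seed 11 --out fix
irfpquant quantify --manifest fix/manifest.csv --out out
cat out/measurements.csv
```

```
mouse_id,day,platform,units,area_px,total_raw,net_total,mean_net,saturated_in_mask,plane_level,plane_raw_level,method
m1,14,SYN,counts,517,2566992.0,757492.0,1465.1682785299806,0,0.4375,3500.0,auto_entropy
m1,17,SYN,counts,529,3437797.0,1394794.8671875,2636.663265004726,0,0.3203125,3862.0078125,auto_entropy
m1,21,SYN,counts,593,5974600.0,3364010.15625,5672.867042580101,0,0.19140625,4402.34375,auto_entropy
m1,24,SYN,counts,593,9379145.0,6107814.171875,10299.855264544689,0,0.140625,5516.578125,auto_entropy
```

Each row is one imaging day: the mask area in pixels, the raw summed
counts inside the mask, the plane-subtracted `net_total`, and the plane
that produced it (`plane_raw_level` is the background level subtracted
per pixel, in raw counts). `net_total` rises from 1.39e6 on day 17 to
6.11e6 on day 24 — a measured 4.38× increase against the generator's
true amplitude ratio of 4.0; the small overshoot is the entropy
plane's truncation of the blob flanks, which shrinks as the tumour
grows (see `docs/methods.md`). Setting the plane at the known body
plateau (`--level`) instead recovers the 4.0 ratio to within 0.1%.

The same pattern works for repeatability (`simulate --kind phantom`
then `phantom`, reporting a CV in percent), dilution plates
(`dilution`, reporting log-log slope and limit of detection) and
detection tables (`detect`). Every run writes a `run_manifest.json`
with the parameters and seed needed to reproduce it byte-for-byte.

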