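# lifesign

Real-time vital-sign detection for evacuation-monitoring wristbands.

In an evacuation (nursing homes, hospitals, schools), responders do not
need a clinical heart-rate trace — they need a fast, robust answer to
one question per person: *is this wristband on a living, moving person?*
`lifesign` implements the three per-window detectors such a wristband
runs, their nonparametric threshold calibration, the 2-bit state fusion
and telemetry codec, plus a seeded synthetic signal generator and an
evaluation harness, so the whole pipeline can be calibrated and
exercised without hardware or downloads.

## The method

All detectors operate on synchronized windows of τ = 4 s (two full
cycles at the 30 BPM detection floor; N_IR = τ·f_s samples).

**Pulse detection** (PPG photodetector counts S_IR at f_s = 1000 Hz):

1. S_AVG = mean(S_IR); S_P = S_IR − S_AVG (DC removal);
2. S_F(m) = Σₙ S_P(n)·e^(−j2πmn/N)   (unnormalized DFT, amplitude spectrum);
3. f_HR = argmax of |S_F| over the pulse band 0.5–4.0 Hz (30–240 BPM),
   S_max = |S_F(f_HR)|;
4. decide H1 ("pulse present") iff S_max ≥ T_h.

The threshold is calibrated from pulse-bearing segments by
Neyman–Pearson-style quantile inversion: for an assumed miss-detection
probability P_MD, T_h solves

    P_MD = Pr(S_max ≤ T_h | H1) = ∫_{S ≤ T_h} f̂_h(S) dS,

where f̂_h is a Gaussian kernel density estimate with Scott's-rule
bandwidth factor h = n^(−1/5) (effective bandwidth h·σ). The CDF of the
mixture is closed-form, so the quantile is found by bracketed root
finding.

**Wear verification**: worn iff S_AVG lies between two KDE quantiles of
the worn-state light level (below: dark background; above: bright
reflector) *and* contact temperature strictly exceeds T_ht = 27 °C.

**Motion detection**: for N_acc = 8 accelerometer triplets per window,
S = mean(|x̄−xᵢ| + |ȳ−yᵢ| + |z̄−zᵢ|); moving iff S strictly exceeds a
threshold (default 0.05 g). Mean subtraction makes S immune to gravity
and bias.

**Fusion**: code = 2·pulse + motion ∈ {0..3} (0 dead/still, 1 dead/moving,
2 alive/still, 3 alive/moving), transmitted as `59000X00` inside a
6-field semicolon message `epoch;locatorMAC;bandMAC;lifesign;RSSI;battery`.

## Worked example

Simulate a worn resting wrist for 60 s and detect per segment:

```sh
$ lifesign simulate --kind ppg --scenario wrist_rest --duration 60 --seed 1 --out ppg.csv
$ lifesign detect --ppg ppg.csv --fs 1000 --threshold 10000 | head -4
segment,start_s,f_hr,s_max,pulse
0,0.0,1.25,1627276.3196315188,True
1,4.0,1.25,1790061.6466751238,True
2,8.0,1.25,1637677.0202437015,True
```

Each row is one 4 s window: the in-band spectral peak sits at 1.25 Hz
(the generator's 72 BPM pulse, to one DFT bin), and its raw amplitude
S_max ≈ 1.6·10⁶ clears the threshold, so a pulse is detected.

Run the full calibration + four-scenario evaluation:

```sh
$ lifesign evaluate --trials 100 --cal-windows 1000 --pmd 0.1 --seed 1 --outdir evalout
worn detection 94.50% | TPR 94.50% TNR 100.00% PPV 100.00% ACC 97.25% F1 0.9717
```

`evalout/calibration_table.csv` shows the assumed-vs-obtained miss
probability after a random half/half split of 1000 worn windows —
obtained tracks assumed across the whole grid:

```
assumed_pmd,threshold,obtained_pmd
0.005,1009851.07,0.004
0.05,1200959.43,0.052
0.2,1425864.86,0.218
```

`evalout/scenario_readings.csv` tabulates the lifesign-code distribution
per scenario: a worn resting wrist reads mostly code 2 (alive, not
moving; the ~P_MD fraction reads 0), a worn moving wrist reads code 3,
and the two not-worn scenarios read 100% code 0 / code 1 — no false
"alive" readings, hence the 100% specificity and precision above.

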