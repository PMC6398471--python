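# kymoxl

Quantitative analysis of how Aurora B phosphorylation tunes the microtubule
depolymerase MCAK, rebuilt as a tested, fully synthetic-data-driven Python
library. It covers the four measurement pipelines such a study needs:

1. **Single-molecule residence-time kinetics** (`kymoxl.kinetics`) —
   detect binding events of individual motors in TIRF kymographs, fit the
   dwell-time distribution with a zero-offset single exponential, and report
   the off-rate as k_off = 1/τ and the on-rate as landings normalized to
   observation time, microtubule length and motor concentration
   (events s⁻¹ µm⁻¹ pM⁻¹).
2. **Microtubule depolymerization rates** (`kymoxl.depoly`) — trace both
   ends of a shrinking microtubule through a kymograph, fit each end's
   shrinkage speed by least squares, and fit rate-versus-concentration
   series with a baseline-offset Hill curve
   v(C) = v₀ + (v_max − v₀)·Cʰ/(Kʰ + Cʰ).
3. **Crosslink–structure validation** (`kymoxl.xlstruct`) — check
   crosslinking-MS residue pairs against atomic structures using the
   Cα–Cα distance limit of the crosslinker (27 Å for BS3), distinguishing
   pairs satisfied within one chain, only between chains, or violated, and
   export linkage-map arc tables.
4. **Quantitative two-condition XL-MS** (`kymoxl.xlquant`) — normalize
   replicate LC-MS runs by a linear-peptide panel total, summarize each
   residue pair by the median over runs, and test condition changes with a
   Welch t-test on log2 intensities.

Every pipeline has a matching generator in `kymoxl.synth` that produces its
inputs with known ground truth (Poisson landings with exponential dwells
rendered into camera frames, shrinking microtubules, toy Cα structures,
labelled crosslink tables, replicate intensity tables), so the whole
package is testable without any external data.

## The statistics at the core

Dwell times recorded on camera are frame-quantized: an event spanning
k frames has measured duration k·Δt, and only events with k ≥ 3 are
retained. For an exponential dwell, memorylessness makes k − 3 exactly
geometric with success probability 1 − e^(−Δt/τ), so the package fits τ by
the discrete truncated MLE

    τ̂ = −Δt / ln(ŝ/(1+ŝ)),   ŝ = mean(k) − 3,

which removes the ≈ Δt/2 bias of the naive shifted-mean estimator — decisive
when Δt is not small against τ (e.g. τ ≈ 39 ms at 15 ms frames).

## Worked example

```bash
python examples/01_residence_time_kinetics.py
```

```
simulating 20 microtubules, 157 s at 16 pM
dwell tau   : 0.648 s  (95% CI 0.620-0.684)
off-rate    : 1.54 1/s  (truth 1.6)
on-rate     : 8.77e-04 events/s/um/pM  (truth 1.0e-03)
events used : 1201
```

The generator planted an off-rate of 1.6 s⁻¹ (mean dwell 0.625 s); the full
detect → filter → fit chain recovers 1.54 s⁻¹ from ~1200 rendered events.
The on-rate sits a little below truth because dwells shorter than about half
a frame never cross the detection threshold — the same detection limit a
real camera has. The other examples
(`02_depolymerization_hill.py`, `03_crosslink_structure_validation.py`,
`04_quantitative_xlms.py`) walk through the remaining pipelines the same
way: build a small synthetic input, run the method, print the recovered
quantities next to the planted truth.

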