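# vtcfret

Single-molecule FRET burst analysis and structural geometry for the VTC
complex — the yeast vacuolar machine (Vtc1:Vtc3:Vtc4, 3:1:1) that
synthesizes inorganic polyphosphate (polyP) and translocates it across the
vacuolar membrane.  Inositol-pyrophosphate messengers (InsP₆ as surrogate
agonist) activate the complex by docking the Vtc4 polymerase domain onto
the trans-membrane channel; this package implements the quantitative chain
behind that conclusion:

* **Synthetic PIE photon streams** (`vtcfret.photon_sim`) — a generative
  model of diffusion smFRET with donor leakage LK, acceptor direct
  excitation Di and detection factor γ embedded exactly, so every
  downstream stage is testable against known ground truth.
* **Burst pipeline** (`vtcfret.burst`) — 1-ms binning, threshold burst
  search, PIE donor-only/acceptor-only exclusion, the corrected per-burst
  efficiency

      E = (F_DA − LK·F_DD − Di·F_AA) / ((F_DA − LK·F_DD − Di·F_AA) + γ·F_DD)

  with defaults LK = 0.13, Di = 0.06, γ = 0.47, plus histogramming and a
  Gaussian-mixture population summary (in-module EM).
* **Förster conversions** (`vtcfret.forster`) — E = 1/(1+(R/R0)⁶) and its
  inverse, R0 = 52 Å for Alexa488/Cy5.
* **Structure geometry** (`vtcfret.structgeom`) — chain stoichiometry,
  Kabsch superposition and domain RMSD, HOLE-style pore-radius profiles
  with channel length and lining residues, trans-membrane helix counting,
  and accessible-volume dye clouds yielding inter-dye distance
  distributions.
* **³¹P-NMR quantification** (`vtcfret.nmr`) — polyP window integrals
  normalized to the external MDP reference (δ = 20.58 ppm, 3.3 mM).

See `docs/methods.md` for the models, defaults and their rationale.

## Worked example

Predict the transfer efficiency at the structure-derived mean inter-dye
distance between the labeling sites on the polymerase domain (K415C) and
the membrane domain (K689C):

```console
$ vtcfret predict-fret --distance 42.6 --r0 52
E(42.6 Å, R0=52.0 Å) = 0.7679
```

0.7679 — i.e. 0.77 — is the efficiency expected if the polymerase domain
sits docked on the channel as in the InsP₆-activated structure.

Run the end-to-end demo (simulate a two-species mixture — broad "inactive"
at E = 0.30 and sharp "activated" at the Förster value above — then burst
search, correct, histogram and fit):

```console
$ vtcfret run --out-dir demo --seed 1 --duration-s 60
1138 FRET bursts; histogram mode 0.7625; report -> demo/report.json
```

The report shows the mixture resolved near its generative truth: component
means 0.329 and 0.765 with weights 0.434/0.566 (truth: 0.30/0.77 at
0.4/0.6), and the histogram mode in the 0.025-wide bin containing the
activated species — the computational restatement of the agonist-driven
shift from a broad low-FRET profile to a sharp, more populated high-FRET
species.

Other subcommands: `simulate`, `bursts`, `hist`, `pore`, `length`,
`tmhelix`, `superpose`, `av-distance`, `stoichiometry`, `nmr-quant`,
`fixtures` (`vtcfret --help` for details).

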