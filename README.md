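# qsar3d

A 3D-QSAR modeling toolkit for phthalate-ester (PAE) toxicity endpoints.
It packages three published endpoint tables (rat oral LD50, 72-h HepG2 IC50,
relative Nrf2 protein content) for a set of 14 phthalate diesters and
implements the full modeling pipeline on top of them:

1. **dataset** — compound registry (SMILES reconstructed from compound
   names), endpoint tables with lg transforms, train/test splits, and the
   published prediction/residual columns for regression testing.
2. **conformers** — ETKDG embedding + MMFF94 minimization (0.005
   kcal/(mol·Å) gradient threshold, 1000-iteration cap), Gasteiger charges,
   Crippen hydrophobicity weights, H-bond donor/acceptor flags, and rigid
   alignment of every molecule onto the DMP template through the shared
   benzene-1,2-dicarboxylate core.
3. **fields** — CoMFA-style Lennard-Jones steric and Coulomb electrostatic
   fields (±30 kcal/mol cutoff, column-mean electrostatics inside the steric
   envelope) and CoMSIA-style Gaussian similarity indices (α = 0.3) for
   S/E/H/D/A properties on a shared 2.0 Å grid; minimum-sigma column
   filtering and block scaling.
4. **pls** — deterministic PLS1 regression, leave-one-out q², component
   selection by maximal LOO q², training statistics (r², SEE, F) and
   per-field contribution percentages.
5. **validation** — the seven-condition Tropsha external acceptance battery,
   external Q² (F1 convention), and seeded Y-randomization.
6. **ad** — leverage in latent-score space, the h* = 3k/n warning threshold,
   standardized residuals and Williams-plot classification.
7. **contours** — StDev·Coefficient contour fields mapped back to the grid
   and 6-connected favorable/unfavorable region extraction.
8. **synthetic** — seeded generators for latent-structure PLS data,
   homologous diester series with chain-length-monotone endpoints, and
   applicability-domain fixtures with planted outliers.

## CLI

```bash
# fit a model on a packaged endpoint table and write all artifacts
qsar3d build --endpoint LD50 --method comfa --out runs/ld50_comfa

# predict from a saved model + descriptor matrix
qsar3d predict --model runs/ld50_comfa/model.json \
    --descriptors runs/ld50_comfa/descriptors.csv.gz --out preds.csv

# external validation battery on an observed/predicted CSV
qsar3d validate --pred pairs.csv --train-mean 4.18

# applicability domain (Williams plot table; --plot writes the figure)
qsar3d ad --model runs/ld50_comfa/model.json \
    --descriptors runs/ld50_comfa/descriptors.csv.gz \
    --residuals runs/ld50_comfa/predictions.csv --out ad.csv

# contour grid map + region summary for one field
qsar3d contours --model runs/ld50_comfa/model.json \
    --descriptors runs/ld50_comfa/descriptors.csv.gz \
    --field CoMFA_S --out-prefix contour_s

# synthetic fixtures (latent | series | ad)
qsar3d simulate --kind latent --seed 1 --out-prefix fixtures/latent
```

`build` accepts a YAML config (`--config run.yaml`) mirroring the
`RunConfig` fields; command-line flags override file values. Every run is
stamped with a hash of its scientific configuration, and reruns with the
same config are bit-identical.

## Notes on fidelity

The original models were fitted with proprietary software whose exact grid
placement, charges and defaults are not reproducible; grid/probe settings
here use the conventional defaults and the cross-validated statistics are
therefore approximate counterparts, not exact reproductions. The packaged
IC50 table's published CoMSIA prediction column is internally inconsistent
for several rows (experimental − predicted ≠ printed residual); these rows
are flagged by `dataset.inconsistent_residual_rows` and left uncorrected.
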