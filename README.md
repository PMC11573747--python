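# scenith

Translation-inhibition metabolic profiling of flow-cytometry data.

Immune-cell function is tightly coupled to energy metabolism, but classical
extracellular-flux assays need purified cells in bulk. SCENITH-style assays
instead use the rate of protein synthesis as a proxy for metabolic activity:
cells are treated with metabolic inhibitors, protein synthesis is read out
per cell by flow cytometry (e.g. as the fluorescence of a click-labelled
noncanonical amino acid incorporated into nascent proteins), and the drop in
signal under each inhibitor reveals which fuel pathways the cells depend on.
This package implements the complete computation for such assays, for
cytometrists and immunometabolism labs: event-level I/O, fluorescent-barcode
demultiplexing of pooled inhibitor conditions, population gating, geometric-MFI
quantification, the dependence calculus with QC flags, donor-level statistics
with PCA — plus a forward simulator of the whole assay so every stage can be
validated by parameter recovery.

## The model

Four conditions are measured per sample: vehicle control (DMSO),
2-deoxy-D-glucose (2-DG, blocks glucose metabolism), oligomycin (blocks
mitochondrial ATP synthase), and both combined (full ATP-synthesis block).
With MFI the geometric mean fluorescence of a gated population:

```
ΔMFI                     = MFI(DMSO) − MFI(2DG+Oligo)
Glucose dependence (%)       = 100 · (MFI(DMSO) − MFI(2DG))   / ΔMFI
Mitochondrial dependence (%) = 100 · (MFI(DMSO) − MFI(Oligo)) / ΔMFI
Glycolytic capacity (%)      = 100 − Mitochondrial dependence
FAO/AAO capacity (%)         = 100 − Glucose dependence
```

Values are reported raw and flagged, never silently clamped: a negative
mitochondrial dependence is a real phenomenon (MITA — mitochondrial
inhibition translation activation), and a small ΔMFI relative to the gMFI
noise floor marks a low-resolution profile (LOW_RESOLUTION flag).

The forward simulator inverts this calculus exactly: translation under each
condition is scaled linearly in the true (g, m), incorporation follows
saturating kinetics, and fluorescence noise is multiplicative lognormal, so
the geometric MFI targets the model signal and recovered (g, m) can be
compared against ground truth.

## Worked example

Simulate one macrophage sample with true glucose dependence 80% and
mitochondrial dependence 30% (5,000 events per condition, pooled with
two-dye barcoding), then run the analysis chain:

```python
import numpy as np
from scenith import (PopulationSpec, SimulationSpec, simulate_experiment,
                     assign_conditions, apply_gates, lineage_gates,
                     geometric_mfi, dependence_profile, CONDITION_ORDER)

pop = PopulationSpec(name="macrophage", n_events=5000, g=80.0, m=30.0,
                     marker_means={"lineage": 1e3})
spec = SimulationSpec.single([pop], seed=1)
table = simulate_experiment(spec).tables[0]
cmap = spec.channel_map()

demux = assign_conditions(table, cmap, spec.barcode.plan)
gated = apply_gates(table, cmap, lineage_gates([pop]))
ncaa = table.column("ncAA")
mfis = {cond.value: geometric_mfi(
            ncaa[(gated.labels == "macrophage")
                 & np.array([c is cond for c in demux.labels])]).gmfi
        for cond in CONDITION_ORDER}
print({k: round(v, 1) for k, v in mfis.items()})
p = dependence_profile(*mfis.values())
print(f"glucose dependence      {p.glucose_dependence:6.1f} %")
print(f"mitochondrial dependence{p.mitochondrial_dependence:6.1f} %")
print(f"glycolytic capacity     {p.glycolytic_capacity:6.1f} %")
print(f"FAO/AAO capacity        {p.faoaao_capacity:6.1f} %")
print(f"dMFI                    {p.delta_mfi:6.1f} a.u.  flags: {sorted(p.flags)}")
```

This prints the per-condition geometric MFIs

```
{'DMSO': 2908.9, '2DG': 795.5, 'Oligo': 2123.7, '2DG+Oligo': 264.8}
```

and the resulting profile

```
glucose dependence        79.9 %
mitochondrial dependence  29.7 %
glycolytic capacity       70.3 %
FAO/AAO capacity          20.1 %
dMFI                    2644.0 a.u.  flags: []
```

— the inhibitors removed 79.9% (glucose) and 29.7% (mitochondrial) of the
translation signal, recovering the simulated ground truth (80, 30) to within
the Monte-Carlo error of 5,000 events, with no QC flags raised.

The same chain is available from the shell via the `scenith` CLI
(`simulate`, `demux`, `gate`, `profile`, `stats`, and the all-in-one `run`
driven by a YAML config; see `scenith --help`).

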