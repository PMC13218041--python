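# condenskit

Analytics for programmable ssDNA folding and DNA/peptide condensates:
sequence library design with palindrome screening, FRET/CD/FRAP/fusion
spectroscopy and kinetics, coarse-grained bead-trajectory statistics, and
primary SAXS analysis — exercised end-to-end on seeded synthetic data with
stored ground truth.

## Modules

| module | what it does |
| --- | --- |
| `condenskit.sequence_design` | shuffled sequence pools, reverse-complement palindrome detection, nested base-pair-maximization stability ranking, chimera assembly, peptide/DNA charge stoichiometry |
| `condenskit.spectro_fret` | FRET efficiency `E = 1 - F_DA/F_D`, Forster distance `d = R0 ((1-E)/E)^(1/6)` (R0 = 5.1 nm default), Boltzmann-sigmoid melt fits, relative ellipticity changes |
| `condenskit.frap_kinetics` | FRAP double normalization against reference/background channels, 0–100 rescaling, `y = a - b c^t` recovery fits, half-recovery times (numeric solve canonical; the published closed form is available for comparison) |
| `condenskit.fusion_dynamics` | aspect ratios from ellipse axes, `AR(t) = 1 + (AR0-1) exp(-t/tau)` relaxation fits, per-condition tau summaries and ratios |
| `condenskit.cg_metrics` | Rg, Shrake-Rupley SASA, min-max metric normalization, k-means state maps, GROMOS conformational clustering with auto-cutoff search, cluster-dispersion stability `log10(Nmax/S)`, empirical terminal-distance FRET score, tight-binding interaction cutoffs/profiles, contact maps, LJ + reaction-field nonbonded energy decomposition |
| `condenskit.saxs_analysis` | Guinier Rg/I(0) with automatic window selection, Kratky transforms, Porod-invariant volumes |
| `condenskit.synthetic_data` | seeded generators for every input class (polymer ensembles, FRAP traces, fusion events, melt curves, Debye/sphere scattering, emission spectra, sequence sets), each returning its ground truth |
| `condenskit.io_cli` | FASTA, multi-frame XYZ, fixed-column GRO, topology/table readers and writers, plus the umbrella CLI |

Conventions: coordinates and lengths in nm (SAXS q grids in 1/Angstrom on
input, interaction cutoffs reported in Angstrom to match convention);
intervals 0-based half-open; all randomness seeded through
`numpy.random.default_rng`.

## CLI

Every analysis is reachable from the `condenskit` entry point; outputs are
JSON on stdout (or files where noted).

```sh
# design: shuffle a pool, screen palindromes, pick the least-structured candidate
condenskit design shuffle input.fasta --n 100 --seed 1 --out pool.fasta
condenskit design palindromes pool.fasta --min-len 6
condenskit design select pool.fasta --min-palindrome 6 --rank 1

# spectroscopy and kinetics
condenskit fret efficiency donor.tsv fret_pair.tsv --r0 5.1
condenskit melt fit melt_curve.tsv
condenskit frap fit trace.tsv --window 30 --closed-form
condenskit fusion summarize ev1.tsv ev2.tsv --conditions a,b

# coarse-grained trajectories (xyz or gro)
condenskit cg rg traj.xyz
condenskit cg cluster traj.xyz --target-fraction 0.5
condenskit cg efret traj.xyz --pairs 0:75
condenskit cg energy traj.gro --topology top.tsv --group-a DNA --group-b PEP

# SAXS
condenskit saxs guinier curve.tsv
condenskit saxs porod curve.tsv

# synthetic data with a ground-truth sidecar
condenskit simulate frap_trace --params '{"a": 70, "b": 65, "c": 0.9}' --seed 3 --out scratch/trace
```

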