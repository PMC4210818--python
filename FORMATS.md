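# File formats

All artifacts are plain text; floats are written with 12 significant digits
so write/read round trips are lossless to formatting precision.

## Trace TSV (`trace_###.tsv`)

Tab-separated with header. One row per frame.

| column       | unit | description                                    |
|--------------|------|------------------------------------------------|
| `time_s`     | s    | sample time (uniform spacing, default 10 s)    |
| `red`        | single-RNA equivalents | intronic-cassette channel    |
| `green`      | single-RNA equivalents | 3'UTR-cassette channel       |
| `nucleus_sd` | a.u. | per-frame nucleus intensity s.d. (optional; used for photobleach correction) |

## Correlation JSON (`correlation.json`)

Top-level keys `Grr`, `Ggg`, `Grg`, `Ggr` (each with `delays` [s], `values`,
`weights` = overlapping-sample-pair counts, and `sem` when bootstrapped)
plus `norm_constant`, the (Grg(dt)+Ggr(dt))/2 estimate the curves were
divided by. `Grg` is red-leading-green at positive delay; `Ggr` is the same
cross-correlation at negative delay.

`correlation.tsv` is a flat view: `delay_s`, `grr`, `ggg`, `grg`, `ggr`.

## Fit JSON (`fit.json`)

`variant`, `params` and `se` (dotted parameter names, e.g. `splice.mean`),
`rss`, `n_points`, `k_params`, `bic`, `success`, `message`, `at_bound`, and
`derived` (pre-release fraction, label ratio, 3'ss-to-end elongation time,
with SEs). `comparison.tsv` ranks all fitted variants by BIC:
`variant`, `bic`, `delta_bic`, `rss`, `k_params`, `params`.

## Slope JSON (`slope.json`)

`fraction`, `se`, `slope_pos`, `slope_neg` (+ SEs), `diagnostic`. Both
slopes are along increasing delay through zero.

## Particle CSV (`particles.csv`)

Comma-separated: `frame`, `x_um`, `y_um`, `channel` (`red`/`green`).
Simulated fields add a ground-truth `species` column (`pre`/`mrna`).
A bicolor particle appears as one `red` and one `green` row.

`ts_track.csv`: `frame`, `x_um`, `y_um` of the transcription site.
`nucleus.csv`: polygon vertices `x_um`, `y_um` (closed implicitly).

## Spatial outputs

`radial_profile.tsv`: `r_lo_um`, `r_hi_um`, `density_ratio`, `sem` — the
particle-to-TS distance density divided by the uniform-in-nucleus null
(`--mode fish` divides the pre-mRNA density by the mRNA density instead).
`spatial.json`: pair/enrichment summary including `sigma_um` and
`post_release_splice_time_s` = sigma^2/(4 D).

## Config YAML

Sections `layout` (nucleotide landmarks), `model` (variant + delay specs +
`k_init`), `acquisition` (`dt`, `duration`, `n_traces`, noise),
`correlation` (`block_size`, `baseline_window`, `n_boot`, `normalize`),
`fit` (`variants`, `max_delay`, `n_draws`, `max_starts`, `slope_window`),
`spatial` (pair radius, bins, exclusion, `D`, emission and lifetime of the
simulated field), and `seed`. Unknown keys are rejected.

## Manifest (`manifest.json`)

`config_hash` (sha256 of the canonical config JSON), `seed`, per-stage
derived `stage_seeds`, the stage list and the files written. Identical
config + seed reproduce identical artifacts byte for byte.
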