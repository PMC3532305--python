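# CSV schemas

All CSV interfaces read and written by the package. Files are plain UTF-8
CSV with a header row.

## Genotypes (long form) — `read_long_csv` / `write_long_csv`

| column | type | meaning |
|---|---|---|
| population | str | population / site label |
| individual | str | individual id, unique within its population |
| locus | str | locus name |
| allele1 | int or empty | first allele size in bp |
| allele2 | int or empty | second allele size in bp |

A genotype is missing when *both* allele columns are empty; a half-filled
row is rejected. The GenePop (.gen) reader/writer carries the same
information; population labels are encoded as `population:individual` ids
so they survive a round trip.

## Site metadata — `read_site_metadata`

| column | type | meaning |
|---|---|---|
| site | str | site label (must match genotype population labels for IBD) |
| latitude | float or DMS str | decimal degrees, or `15° 47' S` style |
| longitude | float or DMS str | decimal degrees, or `47° 53' W` style |
| arrival_year | int, optional | year the species arrived at the site |

## Morphometrics / phenotypes — pipeline `phenotypes` input

| column | type | meaning |
|---|---|---|
| individual | str | individual id |
| site | str | site label |
| sex | str | stratum for outlier screening, MANOVA and P_ST (`m`/`f`) |
| body_length | float | covariate (cm); optional |
| *trait columns* | float | e.g. tarsus, beak_height, beak_width, beak_length (mm); wing, tail (cm) |

## Reflectance spectra (long form) — `process_spectra` input

| column | type | meaning |
|---|---|---|
| id | str | sample id (joined to `individual` by the pipeline) |
| patch | str | plumage patch (`dorsal` / `breast`) |
| replicate | int | replicate measurement index (1–3) |
| wavelength_nm | float | wavelength; every replicate must cover 300–700 nm |
| reflectance_pct | float | % reflectance relative to the white standard |

## Pipeline outputs

- `diversity.csv` — population, n, Na, Ho, UHe, Fis, Ar, Par, group,
  locus_set, rarefaction_g
- `time_correlation.csv` — index, r, df, p
- `group_comparison.csv` — index, group_a, group_b, W, p
- `bottleneck.csv` — population, locus, n_genes, k, UHe, heq_mean, heq_sd,
  heq_median, DH, p_tail
- `fst_dest_<group>.csv` — square matrix, pairwise theta below the
  diagonal, D_est above
- `rst_<group>.csv`, `fst_pvalues_<group>.csv`, `distances_km_<group>.csv`
  — full symmetric matrices
- `mantel.csv` — group, a, b, r, p
- `manova.csv` — sex, pillai, F, df1, df2, p
- `pst_<trait>_<sex>.csv` — ratio, pst, lower, upper
- `pst_summary.csv` — trait, sex, sigma2_b, sigma2_w, pst_at_1,
  critical_ratio, fst_low, fst_high
- `run_log.json` — versions, config echo, per-stage seeds, stage summaries
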