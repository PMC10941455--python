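# Cohort CSV data dictionary

One row per embryo.  Missing values are empty fields.  Header order is
free; all columns below are mandatory.

## Identifiers and outcome

| column | type | description |
|---|---|---|
| `embryo_id` | string | unique embryo identifier |
| `patient_id` | string | cycle/patient identifier (embryos nest in patients) |
| `label` | enum | `BL` (expanded blastocyst on day 5), `nBL`, or `unknown` |

## Woman-related features (6)

| column | units | description |
|---|---|---|
| `age` | years | maternal age |
| `bmi` | kg/m² | body mass index |
| `day3_fsh` | IU/l | serum FSH on cycle day 3 |
| `amh` | ng/ml | anti-Müllerian hormone |
| `afc` | count | antral follicle count |
| `infertility_years` | years | duration of infertility |

## COS-related features (10) — constant within a patient

| column | units | description |
|---|---|---|
| `total_fsh` | IU | total exogenous gonadotropin dose |
| `peak_e2` | pg/ml | peak estradiol |
| `osi` | COCs·1000/IU | ovarian sensitivity index = `n_cocs * 1000 / total_fsh` |
| `n_cocs` | count | retrieved cumulus-oocyte complexes |
| `n_mature` | count | mature (MII) oocytes, ≤ `n_cocs` |
| `maturation_rate` | fraction | `n_mature / n_cocs` |
| `n_fertilized` | count | normally fertilized oocytes, ≤ `n_mature` |
| `fertilization_rate` | fraction | `n_fertilized / n_mature` (configurable to `/ n_cocs`) |
| `n_cleaved` | count | cleaved embryos, ≤ `n_fertilized` |
| `cleavage_rate` | fraction | `n_cleaved / n_fertilized` |

## Embryo-related features (14)

| column | units | description |
|---|---|---|
| `insemination` | enum | `conventional_IVF` or `ICSI` |
| `imcs` | score | Integrated Morphology Cleavage Score on day 2 |
| `tPNa` | h | pronuclear appearance (missing iff conventional IVF) |
| `tPNf` | h | pronuclear fading |
| `t2`, `t3`, `t4`, `t8` | h | completion of cleavage to 2/3/4/8 cells |
| `tPNf_tPNa` | h | `tPNf - tPNa` (missing iff conventional IVF) |
| `t2_tPNf` | h | `t2 - tPNf` |
| `t3_t2` | h | `t3 - t2` |
| `t4_t3` | h | `t4 - t3` |
| `t4_t2` | h | `t4 - t2` |
| `t8_t4` | h | `t8 - t4` |

All event times are hours post-insemination; where present they must be
positive and weakly ordered `tPNa <= tPNf <= t2 <= t3 <= t4 <= t8`, and
each interval must equal the difference of its endpoints (tolerance 1e-6).
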