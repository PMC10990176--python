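# File schemas

All artifacts are plain text (CSV/JSON).  Timestamps are ISO-8601.

## epochs.csv (one row per accelerometer epoch)

| column      | type     | meaning                                   |
|-------------|----------|-------------------------------------------|
| patient_id  | int      | 1-based patient index                      |
| timestamp   | datetime | epoch start (ISO-8601)                     |
| met         | float    | MET value (multiple of resting metabolism) |

## panel.csv (one row per patient-wave)

| column       | type  | meaning                                        |
|--------------|-------|------------------------------------------------|
| patient_id   | int   |                                                |
| wave         | int   | 1..4                                           |
| week         | int   | 1, 3, 6 or 12 (weeks after hospital discharge) |
| tsk_total    | float | TSK-NL Heart total (13..52); empty when missing|
| tsk_missing  | bool  | explicit missingness flag for the TSK record   |
| pa_light     | float | light-intensity minutes/day (MET < 3)          |
| pa_moderate  | float | moderate-intensity minutes/day (3 <= MET <= 6) |
| pa_heavy     | float | heavy-intensity minutes/day (MET > 6)          |
| pa_total     | float | light + moderate + heavy minutes/day           |

## items.csv (one row per returned questionnaire)

patient_id, wave, item_1 .. item_13 (ints in 1..4; the 13 items sum to the
panel's tsk_total for that patient-wave).

## flow.json

Exclusion ledger: stage label -> count, ending in `analysis_sample`, plus
an `empty_analysis_set` flag.

## wave_pa.csv (aggregate stage output)

patient_id, wave, week, pa_light, pa_moderate, pa_heavy, pa_total — weekly
averages (minutes/day) of the measurement weeks; empty cells mean the week
had no wearable days.

## Missing-table sidecar convention

A values CSV never uses sentinel codes; missingness travels in a parallel
boolean mask CSV of identical shape (see `MissingTable.to_csv`).

## Imputation directory

`imputation_001.csv` .. `imputation_NNN.csv` (completed copies),
`mask.csv` (original missingness mask), `manifest.json` (m, iterations,
seed).
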