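# Session log format (`navassess-log v1`)

All files are UTF-8 CSV with a comma separator, `.` decimal point, a header
row, and a version line `# navassess-log v1` above the header.  Floats are
serialized with `%.17g`, so reading a written log reproduces every value
bit-identically.

A cohort lives in one directory:

```
<root>/sessions.csv
<root>/trials.csv
<root>/questionnaires.csv
<root>/motion/<participant_id>__<condition>__<phase>.csv
```

## sessions.csv — one row per participant x condition session

| column                  | type   | meaning                                        |
|-------------------------|--------|------------------------------------------------|
| `participant_id`        | string | opaque participant identifier                   |
| `condition`             | enum   | `immersive` or `semi_immersive`                 |
| `encoding_duration_min` | float  | encoding-phase duration, minutes                |
| `recall_duration_min`   | float  | recall-phase duration, minutes                  |
| `completed`             | enum   | `true`, or `false` for sessions aborted mid-task |

Aborted sessions (e.g. cybersickness dropouts) are representable: `completed`
is `false` and the session may carry fewer than 16 trials.

## trials.csv — one row per object-relocation trial

| column             | type  | meaning                                             |
|--------------------|-------|-----------------------------------------------------|
| `participant_id`   | string| matches sessions.csv                                |
| `condition`        | enum  | matches sessions.csv                                |
| `landmark`         | enum  | `allocentric` or `egocentric` (recall-cue condition)|
| `item_id`          | int   | 1–4                                                 |
| `repetition`       | int   | 1–4 (recall block; landmark is constant per block)  |
| `enc_x`, `enc_z`   | float | encoding item coordinates, virtual units            |
| `rec_x`, `rec_z`   | float | recalled-response coordinates, virtual units        |
| `recall_latency_s` | float | time to replace the item at recall, seconds ≥ 0     |

Coordinates span the horizontal (x, z) plane of the environment; the vertical
y axis never appears in position logs.  Origin and orientation are arbitrary
but must be consistent within a session.  `(item_id, repetition)` is unique
within a session.

## motion/\*.csv — one file per session phase

| column    | type  | meaning                                                   |
|-----------|-------|-----------------------------------------------------------|
| `t_ms`    | int   | milliseconds since phase start; strictly increasing        |
| `pitch_y` | float | toe–heel tilt (forward/backward), dimensionless, ~[-1, 1] |
| `yaw_z`   | float | left–right tilt (rotation), dimensionless, ~[-1, 1]       |

Nominal spacing is 10 ms (100 Hz); validation flags gaps longer than 2 nominal
intervals.

## questionnaires.csv — long format, one row per item response

| column           | type   | meaning                                  |
|------------------|--------|------------------------------------------|
| `participant_id` | string |                                           |
| `condition`      | enum   |                                           |
| `instrument`     | enum   | `SUS` or `ITC_SOPI_NE`                    |
| `item_index`     | int    | 1-based position in the instrument        |
| `response`       | int    | 1–5 Likert; empty cell = item left blank  |

SUS requires exactly 10 fully answered items; the ITC-SOPI negative-effects
vector is length-agnostic and blank items are excluded from its mean score.
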