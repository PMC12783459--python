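# arcade-dmx

Scoring and analysis toolkit for timed arcade-style decision-making sessions.
Participants (or simulated agents) spend a 30-minute budget across a 21-game
arcade; the package derives from each session log:

* **Tickets** — total tickets earned (overall performance);
* **DMX** — a 0–100 decision-quality score that values every second of the
  session by the rank of the occupied game among the player's *learned*
  per-game profitabilities (tickets/second), with unplayed games imputed the
  mean of the observed rates and ties rank-averaged;
* **Games / Switches** — unique games played and transitions between games;

plus questionnaire scoring (7-item cognitive-reflection test, 11-item
open-minded-thinking scale, 18-item need-for-cognition short form),
distributional summaries (quartiles, skewness/kurtosis, coefficient of
variation and its scale-minimum-adjusted variant), pairwise Pearson
correlation tables, and a fixed-effect inverse-variance meta-analysis on the
Fisher-z scale. An agent-based simulator generates sessions and cohorts so
the full pipeline is testable without the VR environment.

## Scoring convention

Each second t is a decision. Using only evidence from strictly before t,
per-game profitabilities are ranked with tie-averaged ranks (1 = best; the
21 ranks always sum to 231) and the occupied game's rank is valued by the
affine map `v = 100 * (21 - rank) / 20`, so the pre-play all-tie state is
worth 50. The final score is the mean of the 1800 per-second values. The
affine map and mean aggregation are this package's documented convention
(order-preserving, with the 0–100 scale and 50-point neutral baseline).
Travel seconds are attributed to the destination game of the in-progress
switch. A rejected "sum" normalization variant (per-second shares summing
to 1) is retained for comparison only.

## CLI

```bash
dmx simulate  --n 60 --seed 17 --out logs/          # sessions + manifest.csv
dmx score     --logs logs/ --normalization rank --out scores.csv
dmx summarize --scores scores.csv --out descriptives.csv
dmx correlate --scores scores.csv --out corr.csv
dmx meta      --studies study1.csv --studies study2.csv --out meta.csv
dmx run       --config config.yaml                  # full pipeline
```

Session logs are plain CSV (one row per play segment:
`participant_id,row_type,game_id,start_s,end_s,tickets`, half-open
0-based second intervals, optional typed summary rows). Study tables for
`dmx meta` carry either `label,r,n` correlation rows or `label,mean,se`
mean rows. Every output CSV gets a JSON provenance sidecar (version, seed,
config hash). Cleaning (`clean_session_log`) removes rows past 1800 s,
prorates segments crossing the limit, strips duplicated terminal summary
rows, and canonicalizes legacy game labels; it is idempotent and applied
automatically by `dmx score`.

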