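# Probabilistic contingency table for the weather-prediction paradigm.
#
# 14 card combinations (every subset of 1-3 of the 4 cards), each with its
# presentation frequency and the conditional probability that the trial's
# outcome is "sun".  Three entries are anchored to printed values of the
# modelled task (cards 1+2 -> 0.90, cards 1+2+3 -> 0.79, card 4 alone ->
# 0.15); the remaining rows are a SYNTHETIC reconstruction in the style of
# the classic task (Knowlton, Squire & Gluck 1994): mirror-symmetric
# sun/rain structure, exactly two equiprobable (0.50) combinations which are
# excluded from analysis, frequencies summing to 1.
provenance: synthetic-reconstruction (printed anchors exact, remainder external-literature style)
cards: 4
combinations:
  - {cards: [1],          frequency: 0.130, p_sun: 0.85}
  - {cards: [2],          frequency: 0.080, p_sun: 0.62}
  - {cards: [3],          frequency: 0.080, p_sun: 0.38}
  - {cards: [4],          frequency: 0.130, p_sun: 0.15}
  - {cards: [1, 2],       frequency: 0.090, p_sun: 0.90}
  - {cards: [1, 3],       frequency: 0.060, p_sun: 0.60}
  - {cards: [1, 4],       frequency: 0.050, p_sun: 0.50}
  - {cards: [2, 3],       frequency: 0.050, p_sun: 0.50}
  - {cards: [2, 4],       frequency: 0.060, p_sun: 0.40}
  - {cards: [3, 4],       frequency: 0.090, p_sun: 0.10}
  - {cards: [1, 2, 3],    frequency: 0.045, p_sun: 0.79}
  - {cards: [1, 2, 4],    frequency: 0.045, p_sun: 0.65}
  - {cards: [1, 3, 4],    frequency: 0.045, p_sun: 0.35}
  - {cards: [2, 3, 4],    frequency: 0.045, p_sun: 0.21}
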