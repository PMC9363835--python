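"""Simulate a small daily weather panel and delineate growing seasons.

Generates 3 synthetic counties x 10 years of sinusoidal-plus-noise
temperature and Markov-chain rainfall, then finds each county's growing
season: the stretch of the year where the probability of a sub-5-degC day
(across the 10 years) stays below 0.2.
"""

from yieldgap import pipeline, season, synthetic

weather = synthetic.generate_weather(counties=3, years=10, seed=42)
print(f"{len(weather)} station-days for {weather['fips'].nunique()} counties\n")

seasons = pipeline.delineate_counties(weather, p_threshold=season.P_THRESHOLD)
summaries = season.summarize_panel(weather, seasons)

print("county  start  end  length   (DOY; season bounded by cold risk)")
for fips, gs in seasons.items():
    print(f"{fips}   {gs.start_doy:5d} {gs.end_doy:4d} {gs.length:6d}")

per_county = summaries.groupby("fips")[["gsr", "gdd_sum"]].mean().round(0)
print("\nmean growing-season rainfall (mm) and accumulated GDD (degC-day):")
print(per_county.to_string())
print(
    "\nA longer, warmer season accumulates more thermal time (GDD); the "
    "seasonal rainfall total (GSR) is the water supply the yield models "
    "work from."
)
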