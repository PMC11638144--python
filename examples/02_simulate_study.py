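"""Generate a synthetic 23-year study at the published scale.

The default configuration uses the published estimates as generating
truth: mean adult survival 0.841 with 8.8% excess first-interval
mortality, per-destination change probability 0.07, initial area
simplex (0.28, 0.24, 0.24, 0.24), trap-dependent recapture, and
geolocator deployment in 2002 and 2009-2014 with reliability 147/182.
"""

import multievent as me

cfg = me.default_paper_config(n_individuals=1104, seed=1)
data, truth, table = me.simulate_dataset(cfg)

deployed = int((data.intra == 2).sum())
reveals = int(((data.inter >= 2) & (data.inter <= 5)).sum())
failed = int((data.inter == 6).sum())
print(f"{data.n_individuals} individuals, {data.n_releases} capture "
      f"events over {data.n_years} years")
print(f"{deployed} geolocators deployed; {reveals + failed} recovered "
      f"({reveals} informative)")
print(f"{table.n_records} wintering-area assignments archived")

both = truth.alive[:, :-1] & truth.alive[:, 1:]
same = ((truth.area[:, :-1] == truth.area[:, 1:]) & both).sum() / both.sum()
print(f"empirical same-area fraction between consecutive winters: "
      f"{same:.3f} (theory: 1 - 3*0.07 = 0.79)")
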