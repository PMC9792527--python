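# Per-hectare rearing-scenario inputs for the Gomishan grow-out site, as
# published: survivor density, mean individual weight, cumulative feed, and
# the monitored biomass and unconsumed-feed rows (carried as inputs because
# the printed values are not exactly derivable from survivors x weight or
# feed x loss fraction at the table's rounding).
"2018":
  area_ha: 830
  loss_frac: 0.30
  fcr: 1.29
  name: "2018"
  checkpoints:
    - {day: 50, survivors_per_ha: 195000, weight_g: 0.6, cum_feed_t_per_ha: 0.094,
       biomass_t_per_ha: 0.117, unconsumed_feed_t_per_ha: 0.037}
    - {day: 80, survivors_per_ha: 185000, weight_g: 8.5, cum_feed_t_per_ha: 2.283,
       biomass_t_per_ha: 1.574, unconsumed_feed_t_per_ha: 0.685}
    - {day: 110, survivors_per_ha: 185000, weight_g: 15.48, cum_feed_t_per_ha: 4.162,
       biomass_t_per_ha: 2.87, unconsumed_feed_t_per_ha: 1.249}
"2021":
  area_ha: 1251
  loss_frac: 0.10
  fcr: 1.22
  name: "2021"
  checkpoints:
    - {day: 50, survivors_per_ha: 81000, weight_g: 0.6, cum_feed_t_per_ha: 0.039,
       biomass_t_per_ha: 0.0487, unconsumed_feed_t_per_ha: 0.0039}
    - {day: 80, survivors_per_ha: 77000, weight_g: 8.5, cum_feed_t_per_ha: 0.918,
       biomass_t_per_ha: 0.656, unconsumed_feed_t_per_ha: 0.092}
    - {day: 110, survivors_per_ha: 77000, weight_g: 15.5, cum_feed_t_per_ha: 1.615,
       biomass_t_per_ha: 1.196, unconsumed_feed_t_per_ha: 0.161}
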