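# Built-in parameterization of the short-term maternal overweight / GDM /
# macrosomia cost model: published perinatal complication probabilities per
# arm, 2011 USA unit costs (USD, payer perspective), and USA demographics.
#
# Complication keys use the cost table's item names verbatim; the alias table
# in gdmcost.params documents how study outcome labels map onto them.
# Percentages may be written with a "%" suffix; they are converted to
# proportions at load time.
schema_version: 1
cost_year: 2011
currency: USD

population:
  population_size: 313847500
  pregnancy_rate_per_1000: 13.68
  condition_incidence: 5.5%

costs:
  routine_normal_cost: 7790   # routine cost, normal pregnancy + vaginal delivery
  entries:
    Child_brachplexus: 1757
    Child_hyperbili: 2006
    Child_hypoglycemia: 2419
    Comp_child_IUFD: 82361
    Mp_child_IUGR: 15065
    Child_macrosomia: 4014
    Child_NICU: 15065
    Child_overweight: 4014
    Child_premature: 3376
    Child_pretermdelivery: 3376
    Child_resp_distress: 3376
    Child_shoulder: 1757
    Mother_anemia: 0
    Mother_bodymass: 0
    Mother_cesarean: 4189
    Mother_episiotomy: 5165
    Mother_gdm: 1786
    Mother_gest: 1786
    Mother_gesthyper: 1786
    Mother_hydramnion: 0
    Mother_hypertension: 1786
    Mother_induction: 5165
    Mother_PIH: 19184
    Mother_pre eclampsia: 19184
    Mother_PROM: 5165
    Mother_shoulder: 950
    Mother_still birth: 0
    Mother_weight gain: 0

probabilities:
  # Mild-GDM trial arms (randomised treatment vs usual care).  The second
  # study block repeats these percentages under treatment/no-treatment
  # labels; its only new datum, brachial plexus injury 6.7% (both arms), is
  # stored once here.  Hydramnion 0.6% and stillbirth 0.4% are the GDM
  # cohort-study add-ons.
  gdm_untreated:      # usual-care arm; the model's conservative GDM base case
    entries:
      Child_hypoglycemia: 15.40%
      Child_hyperbili: 12.90%
      Child_macrosomia: 14.30%      # birth weight > 4000 g
      Child_pretermdelivery: 11.60%
      Child_NICU: 11.60%
      Child_resp_distress: 2.90%
      Child_brachplexus: 6.70%
      Mother_induction: 26.80%
      Mother_cesarean: 33.80%
      Mother_shoulder: 4.00%
      Mother_pre eclampsia: 5.50%
      Mother_gesthyper: 13.60%      # preeclampsia or gestational hypertension
      Mother_hydramnion: 0.60%
      Mother_still birth: 0.40%
    significance:
      Child_hypoglycemia: NS
      Child_hyperbili: NS
      Child_macrosomia: S
      Child_pretermdelivery: NS
      Child_NICU: NS
      Child_resp_distress: NS
      Mother_induction: NS
      Mother_cesarean: S
      Mother_shoulder: S
      Mother_pre eclampsia: S
      Mother_gesthyper: S
  gdm_treated:
    entries:
      Child_hypoglycemia: 16.30%
      Child_hyperbili: 9.60%
      Child_macrosomia: 5.90%
      Child_pretermdelivery: 9.40%
      Child_NICU: 9.00%
      Child_resp_distress: 1.90%
      Child_brachplexus: 6.70%
      Mother_induction: 27.30%
      Mother_cesarean: 26.90%
      Mother_shoulder: 1.50%
      Mother_pre eclampsia: 2.50%
      Mother_gesthyper: 8.60%
      Mother_hydramnion: 0.60%
      Mother_still birth: 0.40%
    significance:
      Child_hypoglycemia: NS
      Child_hyperbili: NS
      Child_macrosomia: S
      Child_pretermdelivery: NS
      Child_NICU: NS
      Child_resp_distress: NS
      Mother_induction: NS
      Mother_cesarean: S
      Mother_shoulder: S
      Mother_pre eclampsia: S
      Mother_gesthyper: S
  # Hospital-delivery registry, obese vs non-obese mothers.
  obese:
    entries:
      Mother_anemia: 1.31%
      Mother_gdm: 3.08%             # insulin-treated diabetes in pregnancy
      Mother_gest: 7.18%            # other diabetes in pregnancy
      Mother_hypertension: 2.23%    # chronic hypertension
      Mother_pre eclampsia: 5.89%
      Mother_PIH: 0.08%             # eclampsia, costed as PIH (alias table)
    significance:
      Mother_anemia: NS
      Mother_gdm: S
      Mother_gest: S
      Mother_hypertension: S
      Mother_pre eclampsia: S
      Mother_PIH: NS
  non_obese:
    entries:
      Mother_anemia: 1.18%
      Mother_gdm: 0.83%
      Mother_gest: 2.18%
      Mother_hypertension: 0.28%
      Mother_pre eclampsia: 2.42%
      Mother_PIH: 0.06%
  normal:
    entries: {}

# Treatment-effect odds ratios for macrosomia / LGA.  Shipped for opt-in use
# only: the base case takes treated and untreated probabilities directly from
# the trial arms above, so applying these as well would double-count the
# treatment effect.
odds_ratios:
  - outcome: macrosomia
    comparison: treatment GDM vs. usual care
    odds_ratio: 0.38
    ci_low: 0.30
    ci_high: 0.49
    source: Horvath
  - outcome: macrosomia
    comparison: no treatment GDM vs. control
    odds_ratio: 2.66
    ci_low: 1.93
    ci_high: 3.67
    source: Langer
  - outcome: macrosomia
    comparison: treatment vs. control
    odds_ratio: 1.13
    ci_low: 0.82
    ci_high: 1.55
    source: Langer
  - outcome: lga
    comparison: no treatment GDM vs. control
    odds_ratio: 3.28
    ci_low: 2.53
    ci_high: 3.67
    source: Langer
  - outcome: lga
    comparison: treatment GDM vs. control
    odds_ratio: 1.06
    ci_low: 0.81
    ci_high: 1.38
    source: Langer

# Delivery-strategy comparison for an estimated fetal weight of 4500 g
# (decision-analysis study); descriptive, never auto-optimised.
strategies:
  elective_induction:
    entries:
      cesarean_delivery: 35%
      shoulder_dystocia_cesarean: 0.3%
      shoulder_dystocia_vaginal: 14.5%
  elective_cesarean:
    entries:
      shoulder_dystocia: 0.1%
  expectant:
    entries:
      cesarean_delivery: 33%
      shoulder_dystocia_cesarean: 0.3%
      shoulder_dystocia_vaginal: 3%
      plexus_injury: 18%
      permanent_injury: 6.7%

# Published per-case base-case cost breakdowns (pregnancy + delivery), used
# by the calibrated arm mode.
calibration:
  normal:
    mother: 7790
    child: 0
  gdm:
    mother: 11794
    child: 3799
  overweight:
    mother: 13047
    child: 5243

options:
  # A cohort study reports a much higher shoulder-dystocia probability than
  # the 4.0% trial value but prints no number; the override stays unset
  # unless a user supplies one.
  shoulder_dystocia_override: null
  # Perinatal mortality is cited as a model input without a printed value.
  perinatal_mortality: 0
  apply_odds_ratios: false
  # Conditional GDM incidence inside the overweight arm (off by default; the
  # two sub-models are costed separately).
  gdm_given_overweight: null
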