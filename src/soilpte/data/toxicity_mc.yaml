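# Toxicity table for the probabilistic (Monte-Carlo) risk engine.
#
# Same structure as the point table.  Two entries differ, reflecting the
# alternative conventions found in the probabilistic soil health-risk
# literature: the dermal reference dose for Co is taken as the
# inhalation-derived 5.7e-6 mg kg^-1 day^-1 (no gastrointestinal absorption
# factor is available for Co), and oral slope factors are restricted to the
# elements with an established oral value (As, Pb, Cr); Co, Cd and Ni are
# carried as inhalation-route carcinogens only.

cr_pathways: [ingestion, inhalation]

elements:
  Hg:
    abs: 0.001
    rfd: {ingestion: 3.0e-4, dermal: 2.1e-5, inhalation: 8.57e-5}
  As:
    abs: 0.03
    rfd: {ingestion: 3.0e-4, dermal: 1.23e-4, inhalation: 3.0e-4}
    sf: {ingestion: 1.5, inhalation: 15.1}
  Zn:
    abs: 0.001
    rfd: {ingestion: 0.3, dermal: 0.06, inhalation: 0.3}
  Pb:
    abs: 0.001
    rfd: {ingestion: 3.5e-3, dermal: 5.25e-4, inhalation: 3.52e-3}
    sf: {ingestion: 8.5e-3}
  Co:
    abs: 0.001
    rfd: {ingestion: 2.0e-2, dermal: 5.7e-6, inhalation: 5.71e-6}
    sf: {inhalation: 9.8}
  Cd:
    abs: 0.001
    rfd: {ingestion: 1.0e-3, dermal: 1.0e-5, inhalation: 1.0e-3}
    sf: {inhalation: 6.3}
  Ni:
    abs: 0.001
    rfd: {ingestion: 2.0e-2, dermal: 5.4e-3, inhalation: 2.06e-2}
    sf: {inhalation: 0.84}
  Cr:
    abs: 0.001
    rfd: {ingestion: 3.0e-3, dermal: 6.0e-5, inhalation: 2.86e-5}
    sf: {ingestion: 0.5, inhalation: 42.0}
  Cu:
    abs: 0.001
    rfd: {ingestion: 4.0e-2, dermal: 1.2e-2, inhalation: 4.02e-2}
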