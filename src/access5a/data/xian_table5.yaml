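# Accessibility evaluation indicator system for basic community elderly-care
# services (Xi'an study): 5 primary / 14 secondary / 37 tertiary indicators
# with entropy-derived weights as published.
version: 1
grade_values: [5, 4, 3, 2, 1]
nodes:
  - {id: A, label: Availability, level: 1, weight: 0.2329}
  - {id: A1, label: Facility layout, level: 2, parent: A, weight: 0.0616}
  - {id: A11, label: Number of community older adult service centers, level: 3, parent: A1, weight: 0.0311}
  - {id: A12, label: Building area of community older adult care service center, level: 3, parent: A1, weight: 0.0305}
  - {id: A2, label: Facility configuration, level: 2, parent: A, weight: 0.0770}
  - {id: A21, label: Number of beds in community older adult service centers, level: 3, parent: A2, weight: 0.0464}
  - {id: A22, label: Number of service facilities in community older adult care service centers, level: 3, parent: A2, weight: 0.0306}
  - {id: A3, label: Resource supply, level: 2, parent: A, weight: 0.0943}
  - {id: A31, label: Types of older adult services provided by community older adult service centers, level: 3, parent: A3, weight: 0.0333}
  - {id: A32, label: Number of older adult care service projects provided by community older adult care service centers, level: 3, parent: A3, weight: 0.0304}
  - {id: A33, label: Number of service personnel in community older adult service centers, level: 3, parent: A3, weight: 0.0306}
  - {id: B, label: Accessibility, level: 1, weight: 0.0637}
  - {id: B1, label: Space reachable, level: 2, parent: B, weight: 0.0283}
  - {id: B11, label: Distance from residence to community older adult care service center, level: 3, parent: B1, weight: 0.0127}
  - {id: B12, label: Convenience level from the residence to the community older adult care service center, level: 3, parent: B1, weight: 0.0156}
  - {id: B2, label: Time achievable, level: 2, parent: B, weight: 0.0354}
  - {id: B21, label: Waiting time for nursing staff's on-site service, level: 3, parent: B2, weight: 0.0184}
  - {id: B22, label: Time consumption from residence to community older adult care service center, level: 3, parent: B2, weight: 0.0170}
  - {id: C, label: Affordability, level: 1, weight: 0.3161}
  - {id: C1, label: Affordability of prices for obtaining life care services, level: 2, parent: C, weight: 0.0820}
  - {id: C11, label: Meal assistance service, level: 3, parent: C1, weight: 0.0202}
  - {id: C12, label: Cleaning assistance service, level: 3, parent: C1, weight: 0.0243}
  - {id: C13, label: Agency service, level: 3, parent: C1, weight: 0.0375}
  - {id: C2, label: Affordable access to medical care services, level: 2, parent: C, weight: 0.1006}
  - {id: C21, label: Rehabilitation nursing services, level: 3, parent: C2, weight: 0.0334}
  - {id: C22, label: Health management services, level: 3, parent: C2, weight: 0.0293}
  - {id: C23, label: Healthcare services, level: 3, parent: C2, weight: 0.0379}
  - {id: C3, label: Affordability of prices for obtaining mental comfort services, level: 2, parent: C, weight: 0.0859}
  - {id: C31, label: Emotional communication services, level: 3, parent: C3, weight: 0.0444}
  - {id: C32, label: Psychological counseling services, level: 3, parent: C3, weight: 0.0415}
  - {id: C4, label: Affordability of prices for cultural and entertainment services, level: 2, parent: C, weight: 0.0476}
  - {id: C41, label: Entertainment, level: 3, parent: C4, weight: 0.0178}
  - {id: C42, label: Education for the older adult, level: 3, parent: C4, weight: 0.0298}
  - {id: D, label: Acceptability, level: 1, weight: 0.1366}
  - {id: D1, label: Acceptance of service content, level: 2, parent: D, weight: 0.0907}
  - {id: D11, label: Acceptance of life-care services, level: 3, parent: D1, weight: 0.0224}
  - {id: D12, label: Acceptance of medical care services, level: 3, parent: D1, weight: 0.0193}
  - {id: D13, label: Acceptance of mental comfort services, level: 3, parent: D1, weight: 0.0267}
  - {id: D14, label: Acceptance of cultural and recreational services, level: 3, parent: D1, weight: 0.0223}
  - {id: D2, label: Acceptance of service modalities, level: 2, parent: D, weight: 0.0459}
  - {id: D21, label: Acceptance of the home-based care service approach, level: 3, parent: D2, weight: 0.0274}
  - {id: D22, label: Acceptance of daycare services, level: 3, parent: D2, weight: 0.0185}
  - {id: E, label: Adaptability, level: 1, weight: 0.2507}
  - {id: E1, label: Satisfaction with facility construction, level: 2, parent: E, weight: 0.0736}
  - {id: E11, label: Satisfaction with the layout of community older adult service facilities, level: 3, parent: E1, weight: 0.0245}
  - {id: E12, label: Satisfaction with the provision of community older adult service facilities, level: 3, parent: E1, weight: 0.0245}
  - {id: E13, label: Satisfaction with the aging-friendly construction of community older adult service centers, level: 3, parent: E1, weight: 0.0246}
  - {id: E2, label: Satisfaction with quality of service, level: 2, parent: E, weight: 0.1318}
  - {id: E21, label: Satisfaction with life care services provided in the community, level: 3, parent: E2, weight: 0.0244}
  - {id: E22, label: Satisfaction with health care services provided in the community, level: 3, parent: E2, weight: 0.0250}
  - {id: E23, label: Satisfaction with mental comfort services provided in the community, level: 3, parent: E2, weight: 0.0352}
  - {id: E24, label: Satisfaction with cultural and recreational services provided by the community, level: 3, parent: E2, weight: 0.0204}
  - {id: E25, label: Satisfaction with service personnel, level: 3, parent: E2, weight: 0.0268}
  - {id: E3, label: Satisfaction with the service environment, level: 2, parent: E, weight: 0.0453}
  - {id: E31, label: Satisfaction with the internal environment of community older adult service centers, level: 3, parent: E3, weight: 0.0244}
  - {id: E32, label: Satisfaction with age-friendly environment in the community, level: 3, parent: E3, weight: 0.0209}
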