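"""Packaged word pools for the synthetic feed generator.

Hermetic, small pools: no external downloads.  Synthetic SSNs generated
elsewhere always start with the digit 9 so they never resemble issued
numbers.
"""

FIRST_NAMES = [
    "JAMES", "MARY", "ROBERT", "PATRICIA", "JOHN", "JENNIFER", "MICHAEL",
    "LINDA", "DAVID", "ELIZABETH", "WILLIAM", "BARBARA", "RICHARD", "SUSAN",
    "JOSEPH", "JESSICA", "THOMAS", "SARAH", "CHRISTOPHER", "KAREN", "CHARLES",
    "LISA", "DANIEL", "NANCY", "MATTHEW", "BETTY", "ANTHONY", "SANDRA",
    "MARK", "MARGARET", "DONALD", "ASHLEY", "STEVEN", "KIMBERLY", "ANDREW",
    "EMILY", "PAUL", "DONNA", "JOSHUA", "MICHELLE", "KENNETH", "CAROL",
    "KEVIN", "AMANDA", "BRIAN", "DOROTHY", "GEORGE", "MELISSA", "TIMOTHY",
    "DEBORAH", "RONALD", "STEPHANIE", "EDWARD", "REBECCA", "JASON", "SHARON",
    "JEFFREY", "LAURA", "RYAN", "CYNTHIA", "JACOB", "KATHLEEN", "GARY",
    "AMY", "NICHOLAS", "ANGELA", "ERIC", "SHIRLEY", "JONATHAN", "ANNA",
    "STEPHEN", "BRENDA", "LARRY", "PAMELA", "JUSTIN", "EMMA", "SCOTT",
    "NICOLE", "BRANDON", "HELEN", "BENJAMIN", "SAMANTHA", "SAMUEL", "KATHERINE",
    "GREGORY", "CHRISTINE", "ALEXANDER", "DEBRA", "PATRICK", "RACHEL",
    "FRANK", "CAROLYN", "RAYMOND", "JANET", "JACK", "MARIA", "DENNIS",
    "OLIVIA", "JERRY", "HEATHER", "TYLER", "DIANE", "AARON", "JULIE",
    "JOSE", "JOYCE", "ADAM", "VICTORIA", "NATHAN", "KELLY", "HENRY",
    "CHRISTINA", "ZACHARY", "LAUREN", "DOUGLAS", "JOAN", "PETER", "EVELYN",
    "KYLE", "JUDITH", "NOAH", "MEGAN", "ETHAN", "ANDREA", "JEREMY", "CHERYL",
]

LAST_NAMES = [
    "SMITH", "JOHNSON", "WILLIAMS", "BROWN", "JONES", "GARCIA", "MILLER",
    "DAVIS", "RODRIGUEZ", "MARTINEZ", "HERNANDEZ", "LOPEZ", "GONZALEZ",
    "WILSON", "ANDERSON", "THOMAS", "TAYLOR", "MOORE", "JACKSON", "MARTIN",
    "LEE", "PEREZ", "THOMPSON", "WHITAKER", "HARRIS", "SANCHEZ", "CLARK",
    "RAMIREZ", "LEWIS", "ROBINSON", "WALKER", "YOUNG", "ALLEN", "KING",
    "WRIGHT", "SCOTT", "TORRES", "NGUYEN", "HILL", "FLORES", "GREEN",
    "ADAMS", "NELSON", "BAKER", "HALL", "RIVERA", "CAMPBELL", "MITCHELL",
    "CARTER", "ROBERTS", "GOMEZ", "PHILLIPS", "EVANS", "TURNER", "DIAZ",
    "PARKER", "CRUZ", "EDWARDS", "COLLINS", "REYES", "STEWART", "MORRIS",
    "MORALES", "MURPHY", "COOK", "ROGERS", "GUTIERREZ", "ORTIZ", "MORGAN",
    "COOPER", "PETERSON", "BAILEY", "REED", "KELLY", "HOWARD", "RAMOS",
    "KIM", "COX", "WARD", "RICHARDSON", "WATSON", "BROOKS", "CHAVEZ",
    "WOOD", "JAMES", "BENNETT", "GRAY", "MENDOZA", "RUIZ", "HUGHES",
    "PRICE", "ALVAREZ", "CASTILLO", "SANDERS", "PATEL", "MYERS", "LONG",
    "ROSS", "FOSTER", "JIMENEZ", "POWELL", "JENKINS", "PERRY", "RUSSELL",
    "SULLIVAN", "BELL", "COLEMAN", "BUTLER", "HENDERSON", "BARNES",
    "OBRIEN", "FISHER", "VASQUEZ", "SIMMONS", "ROMERO", "JORDAN",
    "PATTERSON", "ALEXANDER", "HAMILTON", "GRAHAM", "REYNOLDS", "GRIFFIN",
    "WALLACE", "MORENO", "WEST", "COLE", "HAYES", "BRYANT", "HERRERA",
    "GIBSON", "ELLIS", "TRAN", "MEDINA", "AGUILAR", "STEVENS", "MURRAY",
    "FORD", "CASTRO", "MARSHALL", "OWENS", "HARRISON", "FERNANDEZ",
    "MCDONALD", "WOODS", "WASHINGTON", "KENNEDY", "WELLS", "VARGAS",
]

# facility names share no whole word with the name pools, so a name leaking
# into a report is detectable by word-boundary search
FACILITIES = [
    "UNITY HEALTH CLINIC", "WW HEALTH CLINIC", "FAMILY MEDICAL CENTER",
    "HU HOSPITAL LAB", "GW MEDICAL FACULTY ASSOCIATES",
    "GEORGETOWN UNIVERSITY HOSPITAL LAB", "LABCORP DC", "QUEST DIAGNOSTICS DC",
    "PROVIDENCE HEALTH LAB", "SIBLEY MEMORIAL LAB", "COMMUNITY OF HOPE CLINIC",
    "LA CLINICA DEL PUEBLO", "MARYS CENTER LAB", "BREAD FOR THE CITY CLINIC",
]

RACES = ["Black", "White", "Asian", "Multiracial", "Other"]

TRANSMISSION_RISKS = ["MSM", "Heterosexual", "IDU", "MSM+IDU", "Perinatal", "Other"]

STATES = ["DC", "MD", "VA", "NY", "PA", "FL"]

OI_CONDITIONS = [
    "Pneumocystis pneumonia", "Kaposi sarcoma", "Candidiasis esophageal",
    "Tuberculosis pulmonary", "Cytomegalovirus retinitis", "Toxoplasmosis of brain",
    "Cryptococcosis extrapulmonary", "Mycobacterium avium complex",
]

ARV_DRUGS = [
    "Biktarvy", "Descovy", "Truvada", "Dolutegravir", "Genvoya", "Triumeq",
    "Cabenuva", "Symtuza", "Odefsey", "Juluca",
]

CAUSES_OF_DEATH = [
    "HIV disease", "Cardiovascular disease", "Malignancy", "Overdose",
    "Renal failure", "Unknown",
]
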