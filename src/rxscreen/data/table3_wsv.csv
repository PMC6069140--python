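api_name,casrn,ltd_mg_kg_d,total_uf,srfd_mg_kg_d,wsv_ug_L,rsc
Albuterol,18559-94-9,0.075,100,0.00075,2,0.8
Alendronate,66376-36-1,0.063,300,0.00021,0.6,0.8
Allopurinol,315-30-0,2.50,100,0.025,70,0.8
Alprazolam,28981-97-7,0.0094,1000,0.0000094,0.03,0.8
Amitriptyline,50-48-6,0.74,10000,0.000074,0.2,0.8
Amlodipine,88150-42-9,0.037,100,0.00037,1,0.8
Amoxicillin,26787-78-0,12.5,1000,0.013,40,0.8
Amphetamine salts,-,0.039,3000,0.000013,0.04,0.8
Ampicillin,69-53-4,12.5,3000,0.0042,10,0.8
Atenolol,29122-68-7,0.63,1000,0.00063,2,0.8
Atorvastatin,134523-00-5,0.13,3000,0.000043,0.1,0.8
Azithromycin,83905-01-5,3.13,3000,0.001,3,0.8
Benztropine,86-13-5,0.013,3000,0.0000043,0.01,0.8
Betaxolol,63659-18-7,0.13,1000,0.00013,0.4,0.8
Bisoprolol,66722-44-9,0.6,1000,0.0006,2,0.8
Carisoprodol,78-44-4,9.38,1000,0.0094,30,0.8
Carvedilol,72956-09-3,0.313,300,0.001,3,0.8
Celecoxib,169590-42-5,2.50,1000,0.0025,7,0.8
Cephalexin,15686-71-2,12.5,1000,0.013,40,0.8
Cimetidine,51481-61-9,10,1000,0.01,30,0.8
Ciprofloxacin,85721-33-1,6.25,3000,0.0021,6,0.8
Clarithromycin,81103-11-9,6.25,3000,0.0021,6,0.8
Clavulanate,58001-44-8,3.13,1000,0.0031,9,0.8
Clindamycin,18323-44-9,7.50,3000,0.0025,7,0.8
Clonazepam,1622-61-3,0.013,3000,0.0000043,0.01,0.8
Clonidine,4205-90-7,0.0025,300,0.0000083,0.02,0.8
Clopidogrel,113665-84-2,0.94,300,0.0031,9,0.8
Codeine,76-57-3,0.19,1000,0.00019,0.5,0.8
Cyclobenzaprine,303-53-7,0.19,10000,0.000019,0.05,0.8
Demeclocycline,127-33-3,7,30000,0.00023,0.6,0.8
Diazepam,439-14-5,0.044,300,0.00015,0.4,0.8
Diclofenac,15307-86-5,1.25,300,0.0042,10,0.8
Digoxin,20830-75-5,0.0016,10000,0.00000016,0.0004,0.8
Diltiazem,42399-41-7,1.5,1000,0.0015,4,0.8
Doxepin,1668-19-5,0.94,3000,0.00032,0.9,0.8
Doxycycline,564-25-0,0.91,30000,0.000030,0.08,0.8
Drospirenone,67392-87-4,0.038,10000,0.0000038,0.01,0.8
Duloxetine,116539-59-4,0.50,1000,0.0005,1,0.8
Enalapril,75847-73-3,0.063,300,0.00021,0.6,0.8
Erythromycin,114-07-8,12.5,1000,0.013,40,0.8
Escitalopram,128196-01-0,0.13,3000,0.000043,0.1,0.8
Ezetimibe,163222-33-1,0.125,300,0.00042,1,0.8
Fenofibrate,49562-28-9,0.60,3000,0.0002,0.6,0.8
Fenoprofen,31879-05-7,2.5,3000,0.00083,2,0.8
Fluconazole,86386-73-4,1.25,10000,0.00013,0.4,0.8
Fluoxetine,54910-89-3,0.25,3000,0.000083,0.2,0.8
Furosemide,54-31-9,0.25,300,0.00083,2,0.8
Gabapentin,60142-96-3,11.3,100,0.11,300,0.8
Gemfibrozil,25812-30-0,15,3000,0.005,10,0.8
Glipizide,29094-61-9,0.19,10000,0.000019,0.05,0.8
Glyburide,10238-21-8,0.016,10000,0.0000016,0.004,0.8
Hydrochlorothiazide,58-93-5,0.16,10000,0.000016,0.04,0.8
Hydrocodone,125-29-1,0.25,10000,0.000025,0.07,0.8
Hydrocortisone,50-23-7,0.25,30000,0.0000083,0.02,0.8
Ibuprofen,15687-27-1,20,3000,0.0067,5,0.2
Imipramine,50-49-7,0.37,10000,0.000037,0.1,0.8
Indomethacin,53-86-1,0.63,300,0.0021,6,0.8
Ketoprofen,22071-15-4,0.94,1000,0.00094,3,0.8
Lamotrigine,84057-84-1,2.81,300,0.0094,30,0.8
Levothyroxine,51-48-9,0.0013,300,0.0000043,0.01,0.8
Lisdexamfetamine,608137-32-2,0.38,3000,0.00013,0.4,0.8
Lisinopril,76547-98-3,0.063,3000,0.000021,0.06,0.8
Lomefloxacin,98079-51-7,20,3000,0.0067,20,0.8
Lorazepam,846-49-1,0.025,3000,0.0000083,0.02,0.8
Losartan,114798-26-4,0.63,300,0.0021,6,0.8
Lovastatin,75330-75-5,0.13,10000,0.000013,0.04,0.8
Mefenamic acid,61-68-7,12.5,3000,0.0042,10,0.8
Meloxicam,71125-38-7,0.094,1000,0.000094,0.3,0.8
Memantine,19982-08-2,0.25,1000,0.00025,0.7,0.8
Meprobamate,57-53-4,3.98,1000,0.004,10,0.8
Metformin,657-24-9,14.7,10000,0.0015,4,0.8
Methylphenidate,113-45-1,0.25,1000,0.00025,0.7,0.8
Methylprednisolone,83-43-2,0.05,30000,0.0000017,0.005,0.8
Metoprolol,51384-51-1,0.31,300,0.001,3,0.8
Minocycline,10118-90-8,2.5,30000,0.000083,0.2,0.8
Montelukast,158966-92-8,0.081,100,0.00081,2,0.8
Naproxen,22204-53-1,6.25,1000,0.0063,20,0.8
Nebivolol,118457-14-0,0.031,1000,0.000031,0.09,0.8
Nifedipine,21829-25-4,0.38,1000,0.00038,1,0.8
Norfloxacin,70458-96-7,10,3000,0.0033,10,0.8
Ofloxacin,82419-36-1,5,3000,0.0017,5,0.8
Olanzapine,132539-06-1,0.037,10000,0.0000037,0.01,0.8
Olmesartan medoxomil,144689-63-4,0.25,300,0.00083,2,0.8
Oxycodone,76-42-6,0.25,30000,0.0000083,0.02,0.8
Oxytetracycline,79-57-2,6.25,30000,0.00021,0.6,0.8
Penicillin V,87-08-1,9.38,3000,0.0031,9,0.8
Pentoxyifylline,6493-05-6,5,300,0.017,50,0.8
Pioglitazone,111025-46-8,0.19,10000,0.000019,0.05,0.8
Pravastatin,81093-37-0,0.35,10000,0.000035,0.1,0.8
Prednisolone,50-24-8,0.06,30000,0.000002,0.006,0.8
Prednisone,53-03-2,0.063,30000,0.0000021,0.006,0.8
Pregabalin,148553-50-8,1.88,300,0.0063,20,0.8
Primidone,125-33-7,9.38,3000,0.0031,9,0.8
Progesterone,57-83-0,2.5,30000,0.000083,0.2,0.8
Promethazine,60-87-7,0.23,3000,0.000077,0.2,0.8
Propranolol,525-66-6,0.38,3000,0.00013,0.4,0.8
Propoxyphene,469-62-5,4.88,3000,0.0016,4,0.8
Quetiapine,111974-69-7,0.63,10000,0.000063,0.2,0.8
Ranitidine,66357-35-5,2,100,0.02,60,0.8
Risperidone,106266-06-2,0.0074,3000,0.0000025,0.007,0.8
Rosuvastatin,287714-41-4,0.063,10000,0.0000063,0.02,0.8
Sertraline,79617-96-2,0.31,3000,0.0001,0.3,0.8
Sildenafil,139755-83-2,0.13,1000,0.00013,0.4,0.8
Simvastatin,79902-63-9,0.063,10000,0.0000063,0.02,0.8
Sitagliptin,486460-32-6,1.25,10000,0.00013,0.4,0.8
Sulfadiazine,68-35-9,25,10000,0.0025,7,0.8
Sulfamethizole,144-82-1,12.5,30000,0.00042,1,0.8
Tadalafil,171596-29-5,0.031,300,0.0001,0.3,0.8
Tamsulosin,106133-20-4,0.005,3000,0.0000017,0.005,0.8
Temazepam,846-50-4,0.09,3000,0.00003,0.08,0.8
Tetracycline,60-54-8,18.8,30000,0.00063,2,0.8
Tramadol,27203-92-5,2.50,1000,0.0025,7,0.8
Trazodone,19794-93-5,1.88,10000,0.00019,0.5,0.8
Triamterene,396-01-0,0.47,300,0.0016,4,0.8
Trimethoprim,738-70-5,4.57,3000,0.0015,4,0.8
Valsartan,137862-53-4,1,300,0.0033,9,0.8
Verapamil,52-53-9,2.25,1000,0.0023,6,0.8
Warfarin,81-81-2,0.025,1000,0.000025,0.07,0.8
Zolpidem,82626-48-0,0.063,3000,0.000021,0.06,0.8
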